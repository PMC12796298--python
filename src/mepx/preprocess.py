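"""Outlier removal and assembly of the model-ready feature table.

Raw stimulation tables are reduced to the four analysis features —
MEP amplitude, ISI, delta and rho — in two steps: Tukey IQR fencing on the
amplitudes, then ratio-to-baseline annotation against each session's
surviving single pulses.  The processing order matters: baselines are
computed after cleaning, so an outlying single pulse cannot contaminate
every metric of its session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metrics import annotate_metrics
from .simulate import STIMULATION_COLUMNS, ParameterError

FEATURE_COLUMNS = ["subject_id", "session_id", "group", "isi_ms", "amplitude_uv", "delta", "rho"]

#: Supported scopes for the IQR rule: fences from all amplitudes pooled, or
#: computed separately per subject or per ISI condition.
IQR_SCOPES = ("global", "subject", "isi")


class SchemaError(ValueError):
    """Input table does not conform to the stimulation CSV schema."""


@dataclass
class CleaningReport:
    """Bookkeeping of one IQR cleaning pass."""

    rows_in: int
    rows_removed: int
    rows_out: int
    k: float
    scope: str
    lower_fence: float | None = None
    upper_fence: float | None = None
    removed_indices: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def iqr_filter(amplitudes, k: float = 1.5) -> np.ndarray:
    """Tukey fence keep-mask: keep values in [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type-7), the convention that also
    determines how many rows the default pipeline removes.  Requires at
    least 4 values so that the quartiles are meaningful.
    """
    values = np.asarray(amplitudes, dtype=float)
    if k <= 0:
        raise ParameterError("IQR multiplier k must be > 0")
    if values.size < 4:
        raise ValueError("IQR filtering needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])  # type-7 / linear interpolation
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def build_feature_table(
    raw: pd.DataFrame, k: float = 1.5, scope: str = "global"
) -> tuple[pd.DataFrame, CleaningReport]:
    """Clean a raw stimulation table and annotate excitability metrics.

    Returns the feature table (stimulation schema + delta, rho) and a
    :class:`CleaningReport` with the removed row indices (positions in
    ``raw``).  ``scope`` selects whether the IQR fences are computed over all
    amplitudes pooled (default, the minimal reading of "IQR criteria on MEP
    amplitudes") or separately per subject or per ISI.
    """
    missing = [c for c in STIMULATION_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"raw table is missing required columns: {missing}")
    if scope not in IQR_SCOPES:
        raise ParameterError(f"scope must be one of {IQR_SCOPES}, got {scope!r}")
    bad_group = set(raw["group"].unique()) - {"HC", "MDD"}
    if bad_group:
        raise SchemaError(f"unknown group labels: {sorted(bad_group)}")

    amps = raw["amplitude_uv"].to_numpy(dtype=float)
    lower = upper = None
    if scope == "global":
        keep = iqr_filter(amps, k=k)
        q1, q3 = np.percentile(amps, [25, 75])
        lower, upper = float(q1 - k * (q3 - q1)), float(q3 + k * (q3 - q1))
    else:
        key = raw["subject_id"] if scope == "subject" else raw["isi_ms"]
        keep = np.ones(len(raw), dtype=bool)
        for _, idx in raw.groupby(key).indices.items():
            keep[idx] = iqr_filter(amps[idx], k=k)

    removed = np.flatnonzero(~keep)
    cleaned = raw.loc[keep].reset_index(drop=True)
    features = annotate_metrics(cleaned)[FEATURE_COLUMNS]
    report = CleaningReport(
        rows_in=len(raw),
        rows_removed=int(len(removed)),
        rows_out=len(features),
        k=float(k),
        scope=scope,
        lower_fence=lower,
        upper_fence=upper,
        removed_indices=[int(i) for i in removed],
    )
    return features, report


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    return df[FEATURE_COLUMNS]
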