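"""Ratio-to-baseline cortical-excitability metrics delta and rho.

For a MEP amplitude X and a baseline set of m single-pulse amplitudes
T_1..T_m recorded in the same session:

    rho   = X * m / sum(T_i)        = X / arithmetic_mean(T)
    delta = (X / m) * sum(1 / T_i)  = X / harmonic_mean(T)

Both are dimensionless and invariant under rescaling of the session's
amplitudes.  By the AM-HM inequality delta >= rho, with equality exactly
when all baseline amplitudes coincide.  For a paired pulse they quantify the
intracortical facilitation (ratio > 1) or inhibition (ratio < 1) induced by
the conditioning pulse; a single pulse is, by convention, a member of its
own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class BaselineError(ValueError):
    """The single-pulse baseline of a session is empty or invalid."""


@dataclass(frozen=True)
class BaselineSet:
    """The m single-pulse amplitudes of one session (all strictly positive)."""

    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        if len(amps) == 0:
            raise BaselineError("baseline set must contain at least one amplitude")
        if any(a <= 0 or not np.isfinite(a) for a in amps):
            raise BaselineError("baseline amplitudes must be finite and > 0")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def m(self) -> int:
        return len(self.amplitudes)

    @property
    def arithmetic_mean(self) -> float:
        return float(np.mean(self.amplitudes))

    @property
    def harmonic_mean(self) -> float:
        return float(self.m / np.sum(1.0 / np.asarray(self.amplitudes)))


def _check_amplitude(x: float) -> float:
    x = float(x)
    if x <= 0 or not np.isfinite(x):
        raise BaselineError("MEP amplitude must be finite and > 0")
    return x


def compute_rho(x: float, baseline: BaselineSet | Sequence[float]) -> float:
    """MEP amplitude divided by the arithmetic mean of the baseline set."""
    if not isinstance(baseline, BaselineSet):
        baseline = BaselineSet(tuple(baseline))
    return _check_amplitude(x) / baseline.arithmetic_mean


def compute_delta(x: float, baseline: BaselineSet | Sequence[float]) -> float:
    """MEP amplitude divided by the harmonic mean of the baseline set."""
    if not isinstance(baseline, BaselineSet):
        baseline = BaselineSet(tuple(baseline))
    return _check_amplitude(x) / baseline.harmonic_mean


def annotate_metrics(table: pd.DataFrame, leave_one_out: bool = False) -> pd.DataFrame:
    """Add ``delta`` and ``rho`` columns to a stimulation table.

    The baseline for every row is the set of single pulses (isi_ms == 0) of
    the same session.  By default singles are included in their own baseline;
    with ``leave_one_out=True`` each single pulse is scored against the other
    singles of its session (which then needs at least two singles).

    Raises :class:`BaselineError`, naming the session, if any session has no
    single pulses.
    """
    if (table["amplitude_uv"] <= 0).any():
        raise BaselineError("all amplitudes must be strictly positive")
    out = table.copy()
    is_single = out["isi_ms"] == 0

    singles = out[is_single]
    m = singles.groupby("session_id")["amplitude_uv"].size()
    sum_t = singles.groupby("session_id")["amplitude_uv"].sum()
    sum_inv_t = (1.0 / singles["amplitude_uv"]).groupby(singles["session_id"]).sum()

    empty = set(out["session_id"].unique()) - set(m.index)
    if empty:
        raise BaselineError(
            f"sessions without single pulses, no baseline available: {sorted(empty)}"
        )

    x = out["amplitude_uv"].to_numpy()
    mm = m.reindex(out["session_id"]).to_numpy(dtype=float)
    st = sum_t.reindex(out["session_id"]).to_numpy(dtype=float)
    sit = sum_inv_t.reindex(out["session_id"]).to_numpy(dtype=float)

    if leave_one_out:
        loo = is_single.to_numpy()
        if (mm[loo] < 2).any():
            raise BaselineError("leave-one-out baselines need >= 2 singles per session")
        mm = np.where(loo, mm - 1, mm)
        st = np.where(loo, st - x, st)
        sit = np.where(loo, sit - 1.0 / x, sit)

    out["rho"] = x * mm / st
    out["delta"] = x * sit / mm
    return out
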