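"""Synthetic TMS stimulation-table generator.

Emulates a paired-pulse intracortical facilitation/inhibition (ICF/ICI)
protocol: each session mixes single test pulses with paired pulses at a set
of interstimulus intervals (ISIs), and every pulse yields a peak-to-peak
motor-evoked-potential (MEP) amplitude in microvolts.

The generator is phenomenological: amplitudes are drawn from Gamma
distributions whose scale is modulated multiplicatively by diagnostic group,
by ISI (facilitation > 1, inhibition < 1) and by a log-normal subject-level
factor.  No EMG waveform, motor-threshold staircase or pulse-timing physics
is simulated; stimulation intensities are carried as metadata only.

The default effect sizes are synthetic choices, not estimates from any real
cohort; see the package methods note for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the stimulation-table CSV schema.
STIMULATION_COLUMNS = ["subject_id", "session_id", "group", "isi_ms", "amplitude_uv"]

#: Diagnostic group labels.
GROUPS = ("HC", "MDD")


class ParameterError(ValueError):
    """A configuration value violates its domain (e.g. non-positive scale)."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Pulse counts and ISIs of one ICF/ICI test session.

    Defaults follow the standard paired-pulse protocol: 8 paired pulses at
    each of ISIs 4, 5, 8, 10, 15 and 20 ms, randomly intermixed with 24
    single pulses (72 pulses per session).  Conditioning/test intensities
    (percent of resting motor threshold) are metadata only.
    """

    isis_ms: tuple[int, ...] = (4, 5, 8, 10, 15, 20)
    n_paired_per_isi: int = 8
    n_single: int = 24
    conditioning_intensity_pct_rmt: float = 80.0
    test_intensity_pct_rmt: float = 120.0

    def __post_init__(self) -> None:
        if self.n_single < 1:
            raise ParameterError("n_single must be >= 1")
        if self.n_paired_per_isi < 0:
            raise ParameterError("n_paired_per_isi must be >= 0")
        isis = tuple(int(i) for i in self.isis_ms)
        if any(i <= 0 for i in isis):
            raise ParameterError("ISIs must be strictly positive")
        if len(set(isis)) != len(isis):
            raise ParameterError("ISIs must be unique")
        object.__setattr__(self, "isis_ms", isis)

    @property
    def pulses_per_session(self) -> int:
        return self.n_single + self.n_paired_per_isi * len(self.isis_ms)


@dataclass(frozen=True)
class GroupEffectSpec:
    """Gamma amplitude model for one diagnostic group.

    Single-pulse amplitudes are Gamma(base_shape, base_scale x subject
    multiplier x group_scale_factor); paired-pulse amplitudes additionally
    multiply the scale by ``isi_modulation[isi]`` (ICF > 1, ICI < 1).  The
    subject multiplier is log-normal with ``subject_scale_sd`` on the log
    scale, producing between-subject amplitude heterogeneity.
    """

    base_shape: float
    base_scale: float
    group_scale_factor: float = 1.0
    isi_modulation: Mapping[int, float] = field(default_factory=dict)
    subject_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.base_shape <= 0 or self.base_scale <= 0:
            raise ParameterError("Gamma shape and scale must be strictly positive")
        if self.group_scale_factor <= 0:
            raise ParameterError("group_scale_factor must be strictly positive")
        if any(v <= 0 for v in self.isi_modulation.values()):
            raise ParameterError("ISI modulation factors must be strictly positive")
        if self.subject_scale_sd < 0:
            raise ParameterError("subject_scale_sd must be >= 0")

    def validate_against(self, protocol: ProtocolSpec) -> None:
        if set(self.isi_modulation) != set(protocol.isis_ms):
            raise ParameterError(
                "isi_modulation must be keyed exactly by the protocol ISIs "
                f"{sorted(protocol.isis_ms)}; got {sorted(self.isi_modulation)}"
            )


def default_effects_hc() -> GroupEffectSpec:
    """Healthy-control amplitude model: short-ISI inhibition, long-ISI facilitation.

    Gamma(2, 150 uV) singles (mean 300 uV at 120% RMT), strong short-interval
    intracortical inhibition at 4-5 ms, facilitation peaking at 10-15 ms, and
    a log-normal subject scale factor with sd 0.5.
    """
    return GroupEffectSpec(
        base_shape=2.0,
        base_scale=150.0,
        group_scale_factor=1.0,
        isi_modulation={4: 0.55, 5: 0.60, 8: 0.90, 10: 1.25, 15: 1.35, 20: 1.15},
        subject_scale_sd=0.5,
    )


def default_effects_mdd() -> GroupEffectSpec:
    """MDD amplitude model: reduced inhibition, enhanced facilitation, higher scale.

    Relative to controls the paired/single ratio is shifted upward at every
    ISI (disinhibition at 4-5 ms, stronger facilitation at 10-20 ms) and the
    overall amplitude scale is 15% higher, so diagnostic signal lives both in
    raw amplitudes and — more reliably — in the ratio-to-baseline metrics.
    """
    return GroupEffectSpec(
        base_shape=2.0,
        base_scale=150.0,
        group_scale_factor=1.15,
        isi_modulation={4: 0.80, 5: 0.85, 8: 1.10, 10: 1.55, 15: 1.70, 20: 1.45},
        subject_scale_sd=0.5,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and per-group amplitude models.

    Defaults mirror the study design this generator emulates: 26 MDD and 17
    healthy-control subjects, one session each.
    """

    n_mdd: int = 26
    n_hc: int = 17
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    effects_hc: GroupEffectSpec = field(default_factory=default_effects_hc)
    effects_mdd: GroupEffectSpec = field(default_factory=default_effects_mdd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mdd < 1 or self.n_hc < 1:
            raise ParameterError("each group needs at least one subject")
        self.effects_hc.validate_against(self.protocol)
        self.effects_mdd.validate_against(self.protocol)


def generate_session(
    subject_id: str,
    group: str,
    effects: GroupEffectSpec,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
    session_id: str | None = None,
) -> pd.DataFrame:
    """Simulate one test session and return its stimulation rows.

    Emits exactly ``protocol.n_single`` single pulses (isi_ms = 0) and
    ``protocol.n_paired_per_isi`` paired pulses per ISI, in randomly
    intermixed order.  Amplitudes are Gamma(base_shape, effective scale)
    draws with the effective scale described in :class:`GroupEffectSpec`.
    """
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}, got {group!r}")
    effects.validate_against(protocol)
    if session_id is None:
        session_id = f"{subject_id}_s1"

    subject_mult = float(np.exp(rng.normal(0.0, effects.subject_scale_sd)))
    base = effects.base_scale * effects.group_scale_factor * subject_mult

    isis = np.concatenate(
        [np.zeros(protocol.n_single, dtype=int)]
        + [np.full(protocol.n_paired_per_isi, isi, dtype=int) for isi in protocol.isis_ms]
    )
    scales = np.where(
        isis == 0,
        base,
        base * np.array([effects.isi_modulation.get(int(i), 1.0) for i in isis]),
    )
    amplitudes = rng.gamma(shape=effects.base_shape, scale=scales)
    order = rng.permutation(len(isis))  # "randomly intermixed" pulse order
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id,
            "group": group,
            "isi_ms": isis[order],
            "amplitude_uv": amplitudes[order],
        }
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a full cohort, one session per subject.

    Deterministic for a fixed ``config.seed``: the same config always yields
    the same table, row for row.
    """
    rng = np.random.default_rng(config.seed)
    sessions = []
    for i in range(config.n_mdd):
        sessions.append(
            generate_session(f"mdd_{i + 1:02d}", "MDD", config.effects_mdd, config.protocol, rng)
        )
    for i in range(config.n_hc):
        sessions.append(
            generate_session(f"hc_{i + 1:02d}", "HC", config.effects_hc, config.protocol, rng)
        )
    return pd.concat(sessions, ignore_index=True)[STIMULATION_COLUMNS]


def inject_outliers(
    table: pd.DataFrame,
    fraction: float,
    multiplier: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multiply a random subset of amplitudes to create artificial outliers.

    Each row is selected independently with probability ``fraction``
    (binomial row count).  Returns a modified copy and the positional indices
    of the altered rows, which serve as ground truth when testing outlier
    removal.
    """
    if not 0 <= fraction < 1:
        raise ParameterError("fraction must be in [0, 1)")
    if multiplier < 1:
        raise ParameterError("multiplier must be >= 1")
    out = table.copy()
    hit = np.flatnonzero(rng.random(len(out)) < fraction)
    out.iloc[hit, out.columns.get_loc("amplitude_uv")] *= multiplier
    return out, hit


def write_stimulation_csv(table: pd.DataFrame, path) -> None:
    """Write a stimulation table in the shared CSV schema (UTF-8, '.' decimal)."""
    table[STIMULATION_COLUMNS].to_csv(path, index=False)


def read_stimulation_csv(path) -> pd.DataFrame:
    """Read a stimulation-table CSV, validating the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in STIMULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stimulation table is missing columns: {missing}")
    return df[STIMULATION_COLUMNS]
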