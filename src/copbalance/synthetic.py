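"""Seeded synthetic Sensory Organization Test (SOT) cohorts.

Real posturography cohorts are clinical data and rarely shareable, so this
module generates centre-of-pressure (COP) trials whose *statistical* structure
mirrors a four-class balance-disorder clinic population: class sizes, age
distributions, a slow low-frequency trend riding on the sway, per-condition
sway amplitude growth, and — crucially — a controllable regularity parameter
``lambda`` that sets where each trial sits on the sine-like (regular, low
approximate entropy) to noise-like (irregular, high approximate entropy)
continuum.

Each trial is composed as::

    x(t) = T(t) + A_cond * [ (1 - lambda) * q(t) + lambda * n(t) ]

where ``T`` is a sum of three slow sinusoids inside the trend band (the
removable trend), ``q`` is a quasi-periodic sum of 2-4 sinusoids in the
0.3-1.5 Hz postural-sway band (low entropy), and ``n`` is Gaussian noise
low-pass filtered at 10 Hz (high entropy).  No biomechanical model is
claimed: the generator promises controllable entropy ordering and cohort
shape, nothing more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosisLabel",
    "AgeParams",
    "PatientRecord",
    "CopTrial",
    "CohortConfig",
    "default_config",
    "uniform_regularity",
    "planted_separation_profile",
    "regularity_profile",
    "generate_trial",
    "generate_trial_with_truth",
    "generate_cohort",
]

AXES = ("ML", "AP")
CONDITIONS = (1, 2, 3, 4, 5, 6)

#: Sway band of the quasi-periodic component, Hz.
_SWAY_BAND = (0.3, 1.5)
#: Low-pass cutoff of the noise component, Hz.
_NOISE_CUTOFF = 10.0


class DiagnosisLabel(str, Enum):
    """The four diagnosis classes of the emulated clinic population."""

    NORMAL_BALANCE = "NormalBalance"
    IMBALANCE = "Imbalance"
    TBI = "TBI"
    UVW_RIGHT = "UVWRight"


@dataclass(frozen=True)
class AgeParams:
    """Truncated-normal age distribution for one class (years)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (0 < self.min < self.max):
            raise ValueError(f"invalid age range [{self.min}, {self.max}]")
        if self.sd <= 0:
            raise ValueError("age sd must be positive")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diagnosis: DiagnosisLabel
    age: float


@dataclass(frozen=True)
class CopTrial:
    """One 20 s COP series for a (patient, condition, axis) triple."""

    patient_id: str
    diagnosis: DiagnosisLabel
    condition: int
    axis: str
    samples: np.ndarray
    sampling_rate: float


# Per-class age parameters of the emulated clinic population (years).
_DEFAULT_AGES: Mapping[DiagnosisLabel, AgeParams] = {
    DiagnosisLabel.NORMAL_BALANCE: AgeParams(46.30, 14.27, 8.0, 84.0),
    DiagnosisLabel.IMBALANCE: AgeParams(56.84, 19.48, 6.0, 89.0),
    DiagnosisLabel.TBI: AgeParams(48.51, 15.71, 7.0, 81.0),
    DiagnosisLabel.UVW_RIGHT: AgeParams(61.19, 13.17, 26.0, 85.0),
}

_DEFAULT_SIZES: Mapping[DiagnosisLabel, int] = {
    DiagnosisLabel.NORMAL_BALANCE: 130,
    DiagnosisLabel.IMBALANCE: 185,
    DiagnosisLabel.TBI: 103,
    DiagnosisLabel.UVW_RIGHT: 57,
}

# Sway amplitude grows with SOT condition difficulty (condition 1: eyes open,
# fixed support ... condition 6: sway-referenced vision and support).
_DEFAULT_AMPLITUDE: Mapping[int, float] = {1: 1.0, 2: 1.2, 3: 1.5, 4: 2.0, 5: 2.8, 6: 3.5}

# Default per-class baseline regularity.  Impaired balance is the less
# adaptive, more regular (lower-entropy) system, so TBI sits lowest and
# NormalBalance highest; Imbalance and UVW Right overlap in between.
_DEFAULT_BASE_LAMBDA: Mapping[DiagnosisLabel, float] = {
    DiagnosisLabel.NORMAL_BALANCE: 0.60,
    DiagnosisLabel.IMBALANCE: 0.48,
    DiagnosisLabel.TBI: 0.35,
    DiagnosisLabel.UVW_RIGHT: 0.46,
}


def regularity_profile(
    base: Mapping[DiagnosisLabel, float], slope: float = 0.02
) -> dict[tuple[DiagnosisLabel, int], float]:
    """Expand per-class baseline lambdas into a (class, condition) map.

    ``slope`` adds a mild increase with condition difficulty, reflecting that
    harder conditions elicit more irregular sway.
    """
    return {
        (label, cond): float(np.clip(base[label] + slope * (cond - 1), 0.0, 1.0))
        for label in base
        for cond in CONDITIONS
    }


def uniform_regularity(lam: float) -> dict[tuple[DiagnosisLabel, int], float]:
    """A flat lambda map — every class and condition identical (null cohorts)."""
    return {(label, cond): float(lam) for label in DiagnosisLabel for cond in CONDITIONS}


def planted_separation_profile(
    lo: float = 0.20, hi: float = 0.75
) -> dict[tuple[DiagnosisLabel, int], float]:
    """A lambda map with a planted all-condition gap between NormalBalance
    (``hi``) and TBI (``lo``).

    Imbalance and UVW Right share an alternating profile (``hi`` on odd
    conditions, ``lo`` on even ones), so every pair involving them overlaps
    on half the features: only (NormalBalance, TBI) differs on all 12, which
    makes the pair recoverable by exhaustive screening.
    """
    reg: dict[tuple[DiagnosisLabel, int], float] = {}
    for cond in CONDITIONS:
        reg[(DiagnosisLabel.NORMAL_BALANCE, cond)] = hi
        reg[(DiagnosisLabel.TBI, cond)] = lo
        alt = hi if cond % 2 else lo
        reg[(DiagnosisLabel.IMBALANCE, cond)] = alt
        reg[(DiagnosisLabel.UVW_RIGHT, cond)] = alt
    return reg


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs to produce one seeded cohort."""

    class_sizes: Mapping[DiagnosisLabel, int] = field(
        default_factory=lambda: dict(_DEFAULT_SIZES)
    )
    age_params: Mapping[DiagnosisLabel, AgeParams] = field(
        default_factory=lambda: dict(_DEFAULT_AGES)
    )
    regularity: Mapping[tuple[DiagnosisLabel, int], float] = field(
        default_factory=lambda: regularity_profile(_DEFAULT_BASE_LAMBDA)
    )
    amplitude_factor: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDE)
    )
    trend_band: tuple[float, float] = (0.01, 0.08)
    trend_amplitude: float = 1.0
    sampling_rate: float = 100.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, lam in self.regularity.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"regularity lambda {lam} for {key} outside [0, 1]")
        amps = [self.amplitude_factor[c] for c in CONDITIONS]
        if any(a <= 0 for a in amps):
            raise ValueError("amplitude factors must be positive")
        if any(b < a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitude factors must be non-decreasing in condition")
        if not (0 <= self.trend_band[0] < self.trend_band[1]):
            raise ValueError(f"invalid trend band {self.trend_band}")
        n = self.sampling_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * duration must be an integer sample count")
        for label, size in self.class_sizes.items():
            if size < 1:
                raise ValueError(f"class size for {label} must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study-shaped cohort (475 patients, 100 Hz, 20 s trials)."""
    return replace(CohortConfig(seed=seed), **overrides)


def _sinusoid_sum(
    t: np.ndarray,
    n_tones: int,
    f_band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    freqs = rng.uniform(*f_band, size=n_tones)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_tones)
    amps = rng.uniform(0.5, 1.0, size=n_tones)
    return (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None])).sum(
        axis=0
    )


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _compose_trial(
    diagnosis: DiagnosisLabel,
    condition: int,
    axis: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the (trend, sway, samples) triple for one trial."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be in 1..6, got {condition!r}")
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    lam = config.regularity[(diagnosis, condition)]
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate

    if config.trend_amplitude > 0 and config.trend_band[1] > 0:
        trend = config.trend_amplitude * _sinusoid_sum(t, 3, config.trend_band, rng)
    else:
        # burn the same number of draws so downstream streams stay aligned
        _sinusoid_sum(t, 3, (0.01, 0.08), rng)
        trend = np.zeros(n)

    n_tones = int(rng.integers(2, 5))
    quasi = _unit_sd(_sinusoid_sum(t, n_tones, _SWAY_BAND, rng))

    white = rng.standard_normal(n)
    b, a = sps.butter(4, _NOISE_CUTOFF / (config.sampling_rate / 2.0))
    noise = _unit_sd(sps.filtfilt(b, a, white))

    amp = config.amplitude_factor[condition]
    sway = amp * ((1.0 - lam) * quasi + lam * noise)
    return trend, sway, trend + sway


def generate_trial(
    diagnosis: DiagnosisLabel,
    condition: int,
    axis: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> CopTrial:
    """Generate one COP trial; deterministic given the rng state.

    The trend, quasi-periodic sway and filtered-noise components are drawn
    fresh from ``rng``; the axis only selects an independent random stream,
    it carries no structural asymmetry.
    """
    _, _, samples = _compose_trial(diagnosis, condition, axis, config, rng)
    return CopTrial(
        patient_id="",
        diagnosis=diagnosis,
        condition=condition,
        axis=axis,
        samples=samples,
        sampling_rate=config.sampling_rate,
    )


def generate_trial_with_truth(
    diagnosis: DiagnosisLabel,
    condition: int,
    axis: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[CopTrial, np.ndarray, np.ndarray]:
    """Like :func:`generate_trial` but also returns the injected trend and
    the amplitude-scaled sway component (everything but the trend), so a
    detrender can be scored against the ground truth."""
    trend, sway, samples = _compose_trial(diagnosis, condition, axis, config, rng)
    trial = CopTrial(
        patient_id="",
        diagnosis=diagnosis,
        condition=condition,
        axis=axis,
        samples=samples,
        sampling_rate=config.sampling_rate,
    )
    return trial, trend, sway


def _truncated_normal(params: AgeParams, rng: np.random.Generator) -> float:
    for _ in range(10_000):
        x = rng.normal(params.mean, params.sd)
        if params.min <= x <= params.max:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[CopTrial]]:
    """Generate the full cohort: one patient record plus 12 trials
    (6 conditions x 2 axes) per patient.

    Identical config (including seed) yields a bitwise-identical cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    patients: list[PatientRecord] = []
    trials: list[CopTrial] = []
    idx = 0
    for label in DiagnosisLabel:
        size = config.class_sizes.get(label, 0)
        for _ in range(size):
            pid = f"P{idx:04d}"
            idx += 1
            age = _truncated_normal(config.age_params[label], rng)
            patients.append(PatientRecord(pid, label, age))
            for condition in CONDITIONS:
                for axis in AXES:
                    trial = generate_trial(label, condition, axis, config, rng)
                    trials.append(
                        CopTrial(
                            patient_id=pid,
                            diagnosis=label,
                            condition=condition,
                            axis=axis,
                            samples=trial.samples,
                            sampling_rate=trial.sampling_rate,
                        )
                    )
    logger.info(
        "generated cohort: %d patients, %d trials (seed=%d)",
        len(patients),
        len(trials),
        config.seed,
    )
    return patients, trials
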