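"""Approximate Entropy (ApEn) and the shuffle-surrogate randomness check.

ApEn(m, r, N) measures the regularity of a length-N series: the (log)
conditional probability that runs of m consecutive points that match within
tolerance r still match when extended to m+1 points.  Perfectly repeatable
signals (a sine wave) score near zero; unpredictable ones score higher.

Conventions follow Pincus: Chebyshev (maximum-coordinate) distance between
templates, self-matches included (which keeps every count positive), natural
logarithms (values in nats), and a tolerance r given either in absolute
signal units or as a fraction of the series' SD (population SD, ddof=0).

    phi_m   = mean_i log C_i^m(r),   C_i^m(r) = (# j : d[x(i), x(j)] <= r) / (N - m + 1)
    ApEn    = phi_m - phi_{m+1}

The production path counts template matches with a k-d tree; the brute-force
transcription (`apen_bruteforce`) is a literal double loop kept as the
testing oracle.

The shuffle-surrogate test guards the detrending step: approximate entropy
of a temporally structured series rises under random permutation of its
samples, so a detrended centre-of-pressure series whose ApEn sits clearly
below its shuffled versions' still carries real postural dynamics rather
than filtered noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ApEnParams",
    "ApEnResult",
    "SurrogateReport",
    "correlation_count",
    "apen",
    "apen_bruteforce",
    "surrogate_test",
]


@dataclass(frozen=True)
class ApEnParams:
    """Embedding dimension m, tolerance r, and how r is interpreted.

    ``r_mode="relative"`` resolves r to ``r * SD(series)`` (the field's
    standard choice, default r=0.2); ``"absolute"`` uses r in signal units.
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "relative"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.r_mode not in ("relative", "absolute"):
            raise ValueError("r_mode must be 'relative' or 'absolute'")

    def resolve(self, x: np.ndarray) -> float:
        """Absolute tolerance for a concrete series."""
        if self.r_mode == "absolute":
            return float(self.r)
        return float(self.r * np.std(x))


@dataclass(frozen=True)
class ApEnResult:
    value: float
    params: ApEnParams
    n: int
    r_abs: float


@dataclass(frozen=True)
class SurrogateReport:
    original: ApEnResult
    shuffled_values: list[float]
    n_shuffles: int
    exceedance: float


def _validate(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} too short for m={m} (need N > m + 1)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def correlation_count(x: np.ndarray, i: int, m: int, r_abs: float) -> float:
    """C_i^m(r): the fraction of length-m templates within Chebyshev
    distance ``r_abs`` of template i (0-based), self-match included."""
    x = _validate(x, m)
    n_templates = x.size - m + 1
    if not 0 <= i < n_templates:
        raise IndexError(f"template index {i} out of range [0, {n_templates})")
    if r_abs <= 0:
        raise ValueError("r_abs must be positive")
    templates = sliding_window_view(x, m)
    dist = np.max(np.abs(templates - templates[i]), axis=1)
    return float(np.count_nonzero(dist <= r_abs)) / n_templates


def _phi(x: np.ndarray, m: int, r_abs: float) -> float:
    """Average log correlation sum at embedding dimension m."""
    templates = sliding_window_view(x, m)
    n_templates = templates.shape[0]
    tree = cKDTree(templates)
    counts = tree.query_ball_point(
        templates, r=r_abs, p=np.inf, return_length=True
    )
    return float(np.mean(np.log(counts / n_templates)))


def apen(x: np.ndarray, params: ApEnParams = ApEnParams()) -> ApEnResult:
    """Approximate entropy of a series (nats).

    A zero-variance series with relative r has no meaningful tolerance; by
    the constant-series convention its ApEn is 0 (logged, not raised).
    """
    x = _validate(x, params.m)
    r_abs = params.resolve(x)
    if r_abs == 0.0:
        logger.warning("zero-variance series with relative r: ApEn = 0 by convention")
        return ApEnResult(0.0, params, x.size, 0.0)
    value = _phi(x, params.m, r_abs) - _phi(x, params.m + 1, r_abs)
    return ApEnResult(value, params, x.size, r_abs)


def apen_bruteforce(x: np.ndarray, params: ApEnParams = ApEnParams()) -> ApEnResult:
    """Literal double-loop evaluation of the ApEn definition — the oracle.

    No vectorisation tricks: for each template i, count the templates j
    within Chebyshev distance r, average the log frequencies at m and m+1,
    subtract.  Kept deliberately naive; practical for N up to ~2000.
    """
    x = _validate(x, params.m)
    if x.size > 2000:
        raise ValueError("brute-force oracle limited to N <= 2000")
    r_abs = params.resolve(x)
    if r_abs == 0.0:
        logger.warning("zero-variance series with relative r: ApEn = 0 by convention")
        return ApEnResult(0.0, params, x.size, 0.0)

    def phi(m: int) -> float:
        n_templates = x.size - m + 1
        total = 0.0
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                d = 0.0
                for k in range(m):
                    d = max(d, abs(x[i + k] - x[j + k]))
                if d <= r_abs:
                    count += 1
            total += np.log(count / n_templates)
        return total / n_templates

    value = phi(params.m) - phi(params.m + 1)
    return ApEnResult(value, params, x.size, r_abs)


def surrogate_test(
    x: np.ndarray,
    params: ApEnParams,
    n_shuffles: int,
    rng: np.random.Generator,
) -> SurrogateReport:
    """Compare ApEn of a series against random permutations of its samples.

    The tolerance is resolved once on the original series and reused for
    every shuffle (permutation preserves the SD, so with relative r this is
    only a guard against drift).  ``exceedance`` is the fraction of shuffles
    whose ApEn exceeds the original's; temporally structured series sit at
    or near 1.0, exchangeable ones near 0.5.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    x = _validate(x, params.m)
    original = apen(x, params)
    frozen = ApEnParams(m=params.m, r=original.r_abs, r_mode="absolute") \
        if original.r_abs > 0 else params
    shuffled_values = [
        float(apen(rng.permutation(x), frozen).value) for _ in range(n_shuffles)
    ]
    exceedance = float(np.mean([v > original.value for v in shuffled_values]))
    return SurrogateReport(
        original=original,
        shuffled_values=shuffled_values,
        n_shuffles=n_shuffles,
        exceedance=exceedance,
    )
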