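"""Empirical Mode Decomposition (EMD) by sifting, and EMD-based detrending.

EMD adaptively decomposes a nonstationary signal into intrinsic mode
functions (IMFs) without assuming any basis: each sifting pass identifies the
signal's local extrema, interpolates upper and lower cubic-spline envelopes
through them, and subtracts the envelope mean until the detail behaves like
an IMF.  IMFs are extracted in decreasing-frequency order, so a slow trend
ends up in the last IMFs and the monotonic residual.  Detrending a
centre-of-pressure series therefore amounts to keeping only the first
(highest-frequency) IMFs — by default the first five — and discarding the
rest.

The sifting stop rule is the standard Cauchy-type criterion on successive
iterates,

    sum_t (d_prev(t) - d_curr(t))**2 / sum_t d_prev(t)**2 < epsilon,

with ``epsilon`` defaulting to 3e-5.  Note the energy-ratio normalisation:
the conventional 0.2 threshold belongs to the *pointwise* variant of this
statistic and would stop the energy-ratio form after a single pass,
under-sifting badly; on broadband signals the ratio decays to a plateau
near 1e-5 within a few tens of passes, so 3e-5 with a 30-iteration cap
yields well-separated, properly sifted modes.  Envelopes use cubic splines with the two
nearest extrema mirrored across each boundary, which keeps end swings from
leaking into the low-frequency IMFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "ImfDecomposition",
    "InsufficientExtrema",
    "find_extrema",
    "envelope_mean",
    "sift",
    "decompose",
    "detrend",
]

DEFAULT_EPSILON = 3e-5
DEFAULT_MAX_IMFS = 12
DEFAULT_MAX_ITERATIONS = 30
DETREND_IMFS = 5


class InsufficientExtrema(ValueError):
    """Raised when a signal has too few extrema to build both envelopes;
    signals the caller to terminate the decomposition."""


@dataclass(frozen=True)
class ImfDecomposition:
    """Ordered IMFs (highest frequency first) plus the monotonic residual.

    Invariant: ``sum(imfs) + residual`` reconstructs the input to floating
    precision, because each IMF is subtracted exactly once.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    epsilon: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strictly interior local maxima and minima.

    A plateau (a run of equal values flanked by opposite slopes) contributes
    its midpoint index, which keeps tie-breaking deterministic.  Constant or
    monotone signals have no interior extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(x)
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    turns = np.nonzero(s[1:] != s[:-1])[0]
    maxima, minima = [], []
    for k in turns:
        # slope changes between segments ending at nz[k] and starting at
        # nz[k+1]; the extremum (possibly a plateau) spans nz[k]+1..nz[k+1]
        pos = (nz[k] + 1 + nz[k + 1]) // 2
        if s[k] > 0:
            maxima.append(pos)
        else:
            minima.append(pos)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through (idx, val) with the two nearest knots mirrored
    across each boundary, evaluated on 0..n-1."""
    k = min(2, idx.size)
    left_t = (-idx[:k])[::-1]
    left_v = val[:k][::-1]
    right_t = (2 * (n - 1) - idx[-k:])[::-1]
    right_v = val[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate a knot when an extremum sits at the boundary
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    return CubicSpline(t, v)(np.arange(n))


def envelope_mean(
    x: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes, m(t).

    Raises :class:`InsufficientExtrema` when either envelope would have
    fewer than two knots.
    """
    x = np.asarray(x, dtype=float)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtrema(
            f"need >= 2 maxima and >= 2 minima, got {maxima.size} and {minima.size}"
        )
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return 0.5 * (upper + lower)


def sift(
    x: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> np.ndarray:
    """Extract one candidate IMF from ``x`` by iterative envelope-mean
    subtraction.

    Iterates ``d <- d - m(d)`` until the relative change between successive
    iterates falls below ``epsilon`` or ``max_iterations`` is hit (the latter
    logs a warning and returns the current detail — EMD practice, not an
    error).  Raises :class:`InsufficientExtrema` if the *input* cannot
    support envelopes at all.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = np.asarray(x, dtype=float).copy()
    for _ in range(max_iterations):
        maxima, minima = find_extrema(d)
        try:
            m = envelope_mean(d, maxima, minima)
        except InsufficientExtrema:
            if np.array_equal(d, x):
                raise
            return d  # mid-sift exhaustion: current detail is the IMF
        d_new = d - m
        denom = float(np.sum(d * d))
        if denom == 0.0:
            return d_new
        stat = float(np.sum(m * m)) / denom  # (d_prev - d_curr) == m
        d = d_new
        if stat < epsilon:
            return d
    logger.warning(
        "sifting did not converge within %d iterations (stat >= %.3g)",
        max_iterations,
        epsilon,
    )
    return d


def _is_terminal(x: np.ndarray) -> bool:
    """Residual termination: monotonic or fewer than two interior extrema
    of either kind (no envelopes possible)."""
    maxima, minima = find_extrema(x)
    return maxima.size < 2 or minima.size < 2


def decompose(
    x: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> ImfDecomposition:
    """Full EMD: repeatedly sift an IMF out of the running residual until it
    is monotonic (or nearly so), or ``max_imfs`` have been extracted."""
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short to decompose (need N >= 4)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs and not _is_terminal(residual):
        imf = sift(residual, epsilon=epsilon, max_iterations=max_iterations)
        imfs.append(imf)
        residual = residual - imf
    return ImfDecomposition(imfs=imfs, residual=residual, epsilon=epsilon)


def detrend(
    x: np.ndarray, decomposition: ImfDecomposition, k: int = DETREND_IMFS
) -> np.ndarray:
    """Detrended signal: the sum of the first ``k`` (highest-frequency) IMFs.

    When the decomposition yields ``k`` or fewer IMFs this equals
    ``x - residual`` (everything except the monotonic trend remainder).
    A decomposition with zero IMFs — the input was already trend-only —
    returns the zero signal with a warning.
    """
    x = np.asarray(x, dtype=float)
    if decomposition.n_imfs == 0:
        logger.warning("decomposition has no IMFs; detrended signal is zero")
        return np.zeros_like(x)
    kk = min(k, decomposition.n_imfs)
    out = decomposition.imfs[0].copy()
    for imf in decomposition.imfs[1:kk]:
        out += imf
    return out
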