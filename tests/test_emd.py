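"""Empirical mode decomposition: extrema detection, envelopes, sifting,
full decomposition invariants, and the first-five-IMF detrending rule."""

import numpy as np
import pytest

import copbalance as cb
from copbalance import emd
from copbalance.synthetic import DiagnosisLabel


def brute_extrema(x):
    """Sign-change enumeration oracle (no plateau handling needed for the
    strictly alternating inputs it is used with)."""
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxima.append(i)
        if x[i] < x[i - 1] and x[i] < x[i + 1]:
            minima.append(i)
    return maxima, minima


class TestFindExtrema:
    def test_single_peak_and_trough(self):
        maxima, minima = cb.find_extrema(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))
        assert maxima.tolist() == [1]
        assert minima.tolist() == [3]

    def test_monotone_ramp_has_no_interior_extrema(self):
        maxima, minima = cb.find_extrema(np.arange(10.0))
        assert maxima.size == 0 and minima.size == 0

    def test_constant_signal_has_no_extrema(self):
        maxima, minima = cb.find_extrema(np.zeros(50))
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_contributes_midpoint(self):
        maxima, minima = cb.find_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, 0.0]))
        assert maxima.tolist() == [2]
        assert minima.tolist() == [5]

    def test_one_period_sinusoid_matches_bruteforce(self):
        t = np.linspace(0, 1, 101)
        x = np.sin(2 * np.pi * t + 0.3)
        maxima, minima = cb.find_extrema(x)
        bm, bn = brute_extrema(x)
        assert maxima.tolist() == bm and minima.tolist() == bn
        assert maxima.size == 1 and minima.size == 1


class TestEnvelopeMean:
    def test_sinusoid_mean_is_small_in_interior(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        m = cb.envelope_mean(x, *cb.find_extrema(x))
        assert np.max(np.abs(m[200:-200])) < 0.05

    def test_constant_shift_equivariance(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.5 * t)
        shifted = x + 3.7
        m = cb.envelope_mean(shifted, *cb.find_extrema(shifted))
        assert np.allclose(m[100:-100], 3.7, atol=0.05)

    def test_envelopes_interpolate_extrema_and_rarely_cross(self):
        """Cubic-spline envelopes pass exactly through their own extrema;
        between knots spline overshoot can locally invert the ordering, so
        upper >= lower is asserted for the overwhelming majority of interior
        samples rather than everywhere (a strict everywhere-ordering is not
        a property cubic interpolation can guarantee)."""
        rng = np.random.default_rng(17)
        fractions = []
        for _ in range(100):
            x = np.cumsum(rng.standard_normal(200))
            maxima, minima = cb.find_extrema(x)
            if maxima.size < 2 or minima.size < 2:
                continue
            upper = emd._mirrored_spline(maxima, x[maxima], x.size)
            lower = emd._mirrored_spline(minima, x[minima], x.size)
            np.testing.assert_allclose(upper[maxima], x[maxima], atol=1e-9)
            np.testing.assert_allclose(lower[minima], x[minima], atol=1e-9)
            interior = slice(int(min(maxima[0], minima[0])), int(max(maxima[-1], minima[-1])))
            fractions.append(np.mean(upper[interior] >= lower[interior] - 1e-9))
        assert min(fractions) > 0.9
        assert np.mean(fractions) > 0.98

    def test_too_few_extrema_signals_termination(self):
        x = np.arange(20.0)
        with pytest.raises(cb.InsufficientExtrema):
            cb.envelope_mean(x, *cb.find_extrema(x))


class TestSift:
    def test_huge_epsilon_performs_exactly_one_pass(self):
        t = np.arange(500) / 100.0
        x = np.sin(2 * np.pi * 3 * t) + 0.3 * np.sin(2 * np.pi * 0.5 * t)
        one_pass = x - cb.envelope_mean(x, *cb.find_extrema(x))
        np.testing.assert_allclose(cb.sift(x, epsilon=1e6), one_pass)

    def test_two_tone_first_imf_recovers_fast_tone(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 0.5 * t)
        imf = cb.sift(x)
        interior = slice(100, 1900)
        corr = np.corrcoef(imf[interior], np.sin(2 * np.pi * 5 * t)[interior])[0, 1]
        assert corr > 0.95

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            cb.sift(np.sin(np.arange(100.0)), epsilon=0.0)


class TestDecompose:
    def test_monotone_input_yields_zero_imfs(self):
        x = np.linspace(0.0, 5.0, 100)
        dec = cb.decompose(x)
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residual, x)

    def test_constant_input_yields_zero_imfs(self):
        dec = cb.decompose(np.full(50, 2.5))
        assert dec.n_imfs == 0

    def test_reconstruction_on_seeded_random_signals(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            x = np.cumsum(rng.standard_normal(400))
            dec = cb.decompose(x)
            err = np.max(np.abs(x - dec.reconstruct())) / np.max(np.abs(x))
            assert err < 1e-8

    def test_two_tone_components_recovered(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 0.5 * t)
        dec = cb.decompose(x)
        assert dec.n_imfs >= 2
        interior = slice(100, 1900)
        c_fast = np.corrcoef(dec.imfs[0][interior], np.sin(2 * np.pi * 5 * t)[interior])[0, 1]
        c_slow = np.corrcoef(dec.imfs[1][interior], np.sin(2 * np.pi * 0.5 * t)[interior])[0, 1]
        assert c_fast > 0.9 and c_slow > 0.9

    def test_imf_zero_crossings_and_extrema_nearly_balance(self):
        t = np.arange(2000) / 100.0
        rng = np.random.default_rng(4)
        x = (
            np.sin(2 * np.pi * 6 * t)
            + 0.7 * np.sin(2 * np.pi * 1.1 * t + 1.0)
            + 0.25 * rng.standard_normal(t.size)
        )
        dec = cb.decompose(x)
        for imf in dec.imfs:
            interior = imf[100:-100]
            zc = int(np.count_nonzero(np.diff(np.sign(interior)) != 0))
            maxima, minima = cb.find_extrema(interior)
            n_ext = maxima.size + minima.size
            # at most ~1 apart, with a small relative allowance for the
            # residual riding waves deep sifting leaves on noisy modes
            assert abs(zc - n_ext) <= 2 + 0.02 * max(zc, n_ext)

    def test_mean_zero_crossing_rate_decreases_across_imfs(self):
        t = np.arange(2000) / 100.0
        x = (
            np.sin(2 * np.pi * 8 * t)
            + np.sin(2 * np.pi * 2 * t + 0.5)
            + np.sin(2 * np.pi * 0.4 * t + 1.2)
        )
        dec = cb.decompose(x)
        rates = [
            np.count_nonzero(np.diff(np.sign(imf)) != 0) / imf.size for imf in dec.imfs
        ]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestDetrend:
    def test_k_at_least_n_imfs_equals_input_minus_residual(self):
        rng = np.random.default_rng(12)
        x = np.cumsum(rng.standard_normal(500))
        dec = cb.decompose(x)
        assert 0 < dec.n_imfs
        expected = x - dec.residual
        np.testing.assert_allclose(cb.detrend(x, dec, k=dec.n_imfs), expected, atol=1e-12)
        np.testing.assert_allclose(
            cb.detrend(x, dec, k=dec.n_imfs + 10), expected, atol=1e-12
        )

    def test_zero_imfs_returns_zero_signal(self):
        x = np.linspace(0, 1, 50)
        dec = cb.decompose(x)
        np.testing.assert_array_equal(cb.detrend(x, dec), np.zeros_like(x))

    def test_detrended_signal_tracks_injected_sway_not_trend(self):
        """On synthetic trials the first-five-IMF rule keeps the sway and
        discards the slow trend (the generator knows the ground truth)."""
        cfg = cb.default_config(seed=3)
        rng = np.random.default_rng(42)
        corr_trend, corr_sway = [], []
        for i in range(6):
            trial, trend, sway = cb.generate_trial_with_truth(
                DiagnosisLabel.TBI, (i % 6) + 1, "ML", cfg, rng
            )
            dec = cb.decompose(trial.samples)
            det = cb.detrend(trial.samples, dec)
            corr_trend.append(abs(np.corrcoef(det, trend)[0, 1]))
            corr_sway.append(np.corrcoef(det, sway)[0, 1])
        ok = sum(ct < 0.2 and cs > 0.8 for ct, cs in zip(corr_trend, corr_sway))
        assert ok >= 5
        assert np.mean(corr_trend) < 0.2
        assert np.mean(corr_sway) > 0.8
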