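"""Gaussian window, extrema counting, boundary extension and the sifting loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from hgt import SignalRecord, SynthSpec, gafd, make_ppg_surrogate
from hgt.decompose import (
    ExtensionStyle,
    GafdConfig,
    build_gaussian_window,
    count_local_extrema,
    extend_signal,
    instantaneous_mean,
    window_half_length,
)


class TestGaussianWindow:
    def test_endpoint_ratio_default_alpha(self):
        # endpoint taps at the default shape parameter are ~0.025% of the centre
        win = build_gaussian_window(10, 4.0728)
        ratio = win.coeffs[0] / win.coeffs[win.half_length]
        assert ratio == pytest.approx(np.exp(-(4.0728**2) / 2), rel=1e-12)
        assert 100 * ratio == pytest.approx(0.025, abs=5e-4)

    def test_endpoint_ratio_minimum_alpha_below_five_percent(self):
        win = build_gaussian_window(25, 2.45)
        ratio = win.coeffs[0] / win.coeffs[win.half_length]
        assert ratio < 0.05
        assert ratio == pytest.approx(np.exp(-(2.45**2) / 2), rel=1e-12)

    def test_flat_limit_small_alpha(self):
        win = build_gaussian_window(1, 1e-6)
        np.testing.assert_allclose(win.coeffs, [1 / 3, 1 / 3, 1 / 3], atol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        m=st.integers(min_value=1, max_value=500),
        alpha=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_unit_sum_symmetry_peak(self, m, alpha):
        win = build_gaussian_window(m, alpha)
        assert win.coeffs.size == 2 * m + 1
        assert abs(win.coeffs.sum() - 1.0) < 1e-12
        np.testing.assert_array_equal(win.coeffs, win.coeffs[::-1])
        assert win.coeffs[m] == win.coeffs.max()
        assert np.all(win.coeffs > 0)

    @pytest.mark.parametrize("m,alpha", [(0, 1.0), (-3, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_arguments(self, m, alpha):
        with pytest.raises(ValueError):
            build_gaussian_window(m, alpha)


def _extrema_bruteforce(x):
    """Independent oracle: strict sign-change scan with plateau collapsing."""
    x = np.asarray(x, float)
    count = 0
    last_sign = 0
    for i in range(1, len(x)):
        d = x[i] - x[i - 1]
        if d == 0:
            continue
        s = 1 if d > 0 else -1
        if last_sign != 0 and s != last_sign:
            count += 1
        last_sign = s
    return count


class TestCountLocalExtrema:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([0, 1, 0, -1, 0, 1, 0], 3),
            (list(range(10)), 0),  # monotone ramp
            ([0, 1, 1, 0], 1),  # plateau collapses to one maximum
            ([1, 1, 1, 1], 0),
            ([0, 1], 0),  # too short for an interior
        ],
    )
    def test_hand_counted(self, x, expected):
        assert count_local_extrema(np.asarray(x, float)) == expected

    def test_single_sine_period(self):
        x = np.sin(2 * np.pi * np.arange(100) / 100)
        assert count_local_extrema(x) == _extrema_bruteforce(x) == 2

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=60))
    def test_matches_bruteforce_scan(self, xs):
        x = np.asarray(xs, float)
        assert count_local_extrema(x) == _extrema_bruteforce(x)


class TestWindowHalfLength:
    @pytest.mark.parametrize(
        "n,ne,eps,expected",
        [
            (2000, 40, 1.8, 180),
            (2000, 2, 1.8, None),  # M = 3600 >= N/2 - 1
            (6000, 22, 1.8, 980),
            (100, 0, 1.8, None),  # no extrema left
        ],
    )
    def test_formula_and_termination(self, n, ne, eps, expected):
        assert window_half_length(n, ne, eps) == expected

    def test_degenerate_m_zero_terminates(self):
        # epsilon * N / Ne < 1 -> M = 0 -> terminate
        assert window_half_length(10, 40, 1.8) is None


class TestExtendSignal:
    @pytest.mark.parametrize(
        "style,expected",
        [
            ("constant", [1, 1, 1, 2, 3, 3, 3]),
            ("periodical", [2, 3, 1, 2, 3, 1, 2]),
            ("reflection", [3, 2, 1, 2, 3, 2, 1]),
            ("double_symmetric_reflection", [2, 1, 1, 2, 3, 3, 2]),
        ],
    )
    def test_conventions(self, style, expected):
        out = extend_signal(np.array([1.0, 2.0, 3.0]), 2, style)
        np.testing.assert_array_equal(out, expected)

    @pytest.mark.parametrize("style", list(ExtensionStyle))
    def test_interior_unchanged_and_length(self, style, rng):
        x = rng.normal(size=50)
        m = 7
        out = extend_signal(x, m, style)
        assert out.size == x.size + 2 * m
        np.testing.assert_array_equal(out[m:-m], x)

    def test_reflection_requires_window_shorter_than_signal(self):
        with pytest.raises(ValueError):
            extend_signal(np.arange(5.0), 5, "reflection")


class TestInstantaneousMean:
    def test_constant_preserved(self):
        win = build_gaussian_window(5)
        out = instantaneous_mean(np.full(30, 3.25), win)
        np.testing.assert_allclose(out, 3.25, rtol=1e-14)

    def test_impulse_reproduces_kernel(self):
        win = build_gaussian_window(4)
        x = np.zeros(41)
        x[20] = 1.0
        out = instantaneous_mean(x, win)
        center = 20 - 4  # valid-region offset
        np.testing.assert_allclose(out[center - 4 : center + 5], win.coeffs[::-1], atol=1e-15)

    def test_matches_bruteforce_sum(self, rng):
        # O(N*M) double-loop oracle on many random cases
        for _ in range(100):
            m = int(rng.integers(1, 9))
            n = 64
            win = build_gaussian_window(m, float(rng.uniform(2.5, 6.0)))
            ext = rng.normal(size=n + 2 * m)
            expected = np.array(
                [sum(win.coeffs[m + k] * ext[j + k + m] for k in range(-m, m + 1)) for j in range(n)]
            )
            np.testing.assert_allclose(instantaneous_mean(ext, win), expected, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_mean(np.zeros(10), build_gaussian_window(5))


class TestGafd:
    def test_two_tone_separation(self):
        fs, dur = 100.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        rec = SignalRecord(np.sin(2 * np.pi * 1.2 * t) + np.sin(2 * np.pi * 0.2 * t), fs)
        dec = gafd(rec)
        peaks = []
        for imf in dec.imfs:
            f, p = periodogram(imf, fs=fs)
            peaks.append(f[np.argmax(p)])
        assert any(abs(p - 1.2) <= 0.12 for p in peaks)
        lows = [i for i, p in enumerate(peaks) if abs(p - 0.2) <= 0.02]
        highs = [i for i, p in enumerate(peaks) if abs(p - 1.2) <= 0.12]
        assert lows and highs and min(lows) > max(highs)

    def test_constant_signal_yields_no_imfs(self):
        rec = SignalRecord(np.full(100, 2.0), 10.0)
        dec = gafd(rec)
        assert dec.imfs == []
        np.testing.assert_array_equal(dec.residual, rec.samples)
        assert dec.stop_reason == "window_bound"

    def test_reconstruction_identity(self, rng):
        for _ in range(10):
            rec = SignalRecord(rng.normal(size=512), 100.0)
            dec = gafd(rec)
            err = np.max(np.abs(rec.samples - dec.reconstruction()))
            assert err <= 1e-9 * np.max(np.abs(rec.samples))

    def test_spectral_ordering_nonincreasing(self, rng):
        # broadband input: periodogram-peak frequency never increases with IMF index
        rec = SignalRecord(rng.normal(size=4000), 100.0)
        dec = gafd(rec)
        assert dec.n_imfs >= 2
        peaks = []
        for imf in dec.imfs:
            f, p = periodogram(imf, fs=rec.fs)
            peaks.append(f[np.argmax(p)])
        assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_shift_equivariance_periodic_input(self):
        # circularly shifting a periodic signal shifts the IMFs (periodical extension)
        fs = 50.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        cfg = GafdConfig(extension_style="periodical")
        shift = 100  # samples; both tones are periodic over the record
        d0 = gafd(SignalRecord(x, fs), cfg)
        d1 = gafd(SignalRecord(np.roll(x, shift), fs), cfg)
        assert d0.n_imfs == d1.n_imfs
        interior = slice(200, 800)
        for a, b in zip(d0.imfs, d1.imfs):
            np.testing.assert_allclose(np.roll(a, shift)[interior], b[interior], atol=5e-2)

    def test_nan_input_rejected(self):
        samples = np.ones(100)
        samples[3] = np.nan
        with pytest.raises(ValueError):
            SignalRecord(samples, 10.0)

    def test_diagnostics_recorded(self, surrogate_12bpm):
        rec, _, _ = surrogate_12bpm
        dec = gafd(rec)
        assert len(dec.windows) == dec.n_imfs
        assert dec.rounds[-1].stop_reason is not None
        assert all(r.stop_reason is None for r in dec.rounds[:-1])


class TestGafdConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epsilon": 1.0},
            {"epsilon": 3.5},
            {"alpha": 2.0},
            {"max_imfs": 0},
            {"energy_ratio_threshold": -1.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            GafdConfig(**kwargs)

    def test_defaults_match_documented_values(self):
        cfg = GafdConfig()
        assert cfg.alpha == 4.0728
        assert cfg.epsilon == 1.8
        assert cfg.extension_style is ExtensionStyle.DOUBLE_SYMMETRIC_REFLECTION
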