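"""Time- and frequency-domain variability: Parseval normalization,
band integration against an independent direct-DFT oracle, and recovery
of injected oscillations through the full resample/detrend/FFT chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemovar import (
    BeatSegment,
    EvenSeries,
    TachogramSpec,
    analyze_variability,
    band_power,
    compute_psd,
    detrend_linear,
    resample_even,
    simulate_tachogram,
    time_domain,
)


def direct_dft_psd(x: np.ndarray, rate: float):
    """O(n^2) direct Fourier sum with the same one-sided Parseval
    normalization; independent oracle for the FFT path."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    j = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, j) / n)
    spec = basis @ x
    power = np.abs(spec) ** 2 / n**2
    power[1 : (n + 1) // 2] *= 2.0
    return k * rate / n, power / (rate / n)


class TestTimeDomain:
    def test_constant_series_has_zero_variance(self):
        sd, var = time_domain([np.full(100, 150.0)])
        assert sd == 0.0 and var == 0.0

    def test_sinusoid_variance(self):
        t = np.arange(2000) * 0.15
        sd, var = time_domain([150.0 + 10.0 * np.sin(2 * np.pi * 0.4 * t)])
        assert var == pytest.approx(50.0, rel=0.05)

    def test_two_point_hand_computation(self):
        sd, var = time_domain([np.array([140.0, 160.0])])
        assert var == pytest.approx(200.0)
        assert sd == pytest.approx(np.sqrt(200.0))

    def test_segment_averaging(self):
        segs = [np.array([140.0, 160.0]), np.array([100.0, 104.0])]
        sd, var = time_domain(segs)
        assert var == pytest.approx((200.0 + 8.0) / 2)
        assert sd == pytest.approx((np.sqrt(200.0) + np.sqrt(8.0)) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_domain([])


class TestResampleEven:
    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.arange(40) / 10.0
        vals = 2.0 - 0.3 * t + 0.05 * t**2 - 0.01 * t**3
        out = resample_even(t, vals, fine_rate=10.0, out_rate=10.0)
        grid = t[0] + np.arange(len(out.values)) / 10.0
        np.testing.assert_allclose(
            out.values, 2.0 - 0.3 * grid + 0.05 * grid**2 - 0.01 * grid**3, rtol=1e-10
        )

    def test_constant_series_stays_constant(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 60, 300))
        out = resample_even(t, np.full(300, 7.0), fine_rate=250.0, out_rate=10.0)
        assert np.allclose(out.values, 7.0, atol=1e-6)

    def test_sinusoid_amplitude_preserved(self):
        # 0.4 Hz sinusoid sampled at irregular beat-like times
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.12, 0.18, 2000))
        vals = 10.0 * np.sin(2 * np.pi * 0.4 * t)
        out = resample_even(t, vals, fine_rate=250.0, out_rate=10.0)
        grid = t[0] + np.arange(len(out.values)) / 10.0
        ref = 10.0 * np.sin(2 * np.pi * 0.4 * grid)
        interior = slice(50, -50)  # ignore filter edge transients
        amp_err = np.abs(out.values[interior] - ref[interior]).max() / 10.0
        assert amp_err < 0.02

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            resample_even(np.array([0.0, 0.2, 0.1, 0.4]), np.zeros(4))


class TestDetrend:
    def test_exact_line_maps_to_zero(self):
        t = np.arange(100) / 10.0
        out = detrend_linear(EvenSeries(values=3.0 + 0.7 * t, rate=10.0))
        assert np.abs(out.values).max() < 1e-9

    def test_sinusoid_plus_line_recovered(self):
        t = np.arange(1000) / 10.0
        sin = 5.0 * np.sin(2 * np.pi * 0.4 * t)
        out = detrend_linear(EvenSeries(values=sin + 2.0 - 0.3 * t, rate=10.0))
        assert np.abs(out.values - sin).max() < 0.25  # LS line absorbs a bit of the sinusoid
        slope = np.polyfit(t, out.values, 1)[0]
        assert abs(slope) < 1e-9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        once = detrend_linear(EvenSeries(values=x, rate=10.0))
        twice = detrend_linear(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)
        assert abs(once.values.mean()) < 1e-9


class TestPsdAndBands:
    def test_zero_series_zero_psd(self):
        s = EvenSeries(values=np.zeros(64), rate=10.0, detrended=True)
        _, psd = compute_psd(s)
        assert np.all(psd == 0.0)

    def test_exact_bin_sinusoid_parseval(self):
        n, rate = 1000, 10.0
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 0.4 * t)  # 0.4 Hz = bin 40 exactly
        f, psd = compute_psd(EvenSeries(values=x - x.mean(), rate=rate, detrended=True))
        total = band_power(f, psd, 0.0, rate / 2)
        assert total == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("window", ["boxcar", "hann"])
    def test_parseval_white_noise(self, window, rng):
        x = rng.standard_normal(3000)
        s = detrend_linear(EvenSeries(values=x, rate=10.0))
        f, psd = compute_psd(s, window=window)
        total = band_power(f, psd, 0.0, 5.0)
        if window == "boxcar":
            assert total == pytest.approx(np.mean(s.values**2), rel=1e-6)
        else:
            # tapering redistributes power; normalization keeps it close
            assert total == pytest.approx(np.mean(s.values**2), rel=0.1)

    def test_band_additivity(self, rng):
        x = rng.standard_normal(2048)
        s = detrend_linear(EvenSeries(values=x, rate=10.0))
        f, psd = compute_psd(s)
        total = band_power(f, psd, 0.0, 5.0)
        parts = (
            band_power(f, psd, 0.0, 0.2)
            + band_power(f, psd, 0.2, 0.75)
            + band_power(f, psd, 0.75, 4.0)
            + band_power(f, psd, 4.0, 5.0)
        )
        assert parts == pytest.approx(total, rel=1e-9)

    @pytest.mark.parametrize("n", [64, 257, 512])
    def test_band_powers_match_direct_dft_oracle(self, n, rng):
        x = rng.standard_normal(n)
        s = detrend_linear(EvenSeries(values=x, rate=10.0))
        f, psd = compute_psd(s)
        f2, psd2 = direct_dft_psd(s.values, 10.0)
        np.testing.assert_allclose(f, f2, atol=1e-12)
        for lo, hi in [(0.2, 0.75), (0.75, 4.0), (0.0, 5.0)]:
            assert band_power(f, psd, lo, hi) == pytest.approx(
                band_power(f2, psd2, lo, hi), rel=1e-9
            )

    def test_sinusoid_band_assignment(self):
        n, rate = 3000, 10.0
        t = np.arange(n) / rate
        for freq, band in [(0.4, "lf"), (1.5, "hf")]:
            x = 10.0 * np.sin(2 * np.pi * freq * t)
            s = detrend_linear(EvenSeries(values=x, rate=rate))
            f, psd = compute_psd(s)
            lf = band_power(f, psd, 0.2, 0.75)
            hf = band_power(f, psd, 0.75, 4.0)
            inside, outside = (lf, hf) if band == "lf" else (hf, lf)
            assert inside == pytest.approx(50.0, rel=0.02)
            assert outside < 0.02 * inside

    def test_short_series_rejected(self):
        s = EvenSeries(values=np.zeros(8), rate=10.0, detrended=True)
        with pytest.raises(ValueError):
            compute_psd(s)

    def test_band_outside_support_rejected(self):
        s = EvenSeries(values=np.zeros(64), rate=10.0, detrended=True)
        f, psd = compute_psd(s)
        with pytest.raises(ValueError, match="support"):
            band_power(f, psd, 6.0, 8.0)


class TestAnalyzeVariability:
    def _segment(self, spec):
        tacho = simulate_tachogram(spec)
        pi = np.append(np.nan, np.diff(tacho.times) * 1000.0)
        sap = np.full(len(tacho.times), 180.0)
        return BeatSegment(times=tacho.times, pi=pi, sap=sap)

    def test_identical_segments_average_to_single_result(self):
        seg = self._segment(TachogramSpec(base_pi=150.0, amp_lf=10.0, duration=300.0))
        one_hrv, _ = analyze_variability([seg])
        three_hrv, _ = analyze_variability([seg, seg, seg])
        assert three_hrv.lf == pytest.approx(one_hrv.lf)
        assert three_hrv.var == pytest.approx(one_hrv.var)
        assert three_hrv.n_segments == 3

    def test_injected_lf_and_hf_power_recovered(self):
        seg = self._segment(
            TachogramSpec(base_pi=150.0, amp_lf=10.0, amp_hf=6.0, duration=300.0, seed=4)
        )
        hrv, _ = analyze_variability([seg], "methods")
        assert hrv.lf == pytest.approx(50.0, rel=0.10)
        assert hrv.hf == pytest.approx(18.0, rel=0.10)

    def test_noisy_recovery_within_ten_percent(self):
        seg = self._segment(
            TachogramSpec(base_pi=150.0, amp_lf=10.0, noise_sd=2.0, duration=300.0, seed=8)
        )
        hrv, _ = analyze_variability([seg], "methods")
        assert hrv.lf == pytest.approx(50.0, rel=0.10)

    def test_group_variance_target(self):
        # generator calibrated to a total PI variance near 54 ms^2
        seg = self._segment(
            TachogramSpec(
                base_pi=170.0, amp_lf=2.52, amp_hf=3.45, noise_sd=6.69, duration=300.0, seed=12
            )
        )
        hrv, _ = analyze_variability([seg], "table2")
        assert hrv.var == pytest.approx(54.0, rel=0.15)

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            analyze_variability([])
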