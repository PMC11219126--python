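"""Filter design, application modes, stability, coefficient round-trip."""

import numpy as np
import pytest

from gazefilt import (GazeTrace, DesignedFilter, LowpassSpec, TapEstimateSpec,
                      design_savgol, design_butterworth_lowpass,
                      design_fir_lowpass, estimate_fir_taps, apply_filter,
                      is_stable, save_filter, load_filter)

FS = 1000.0


def sinusoid_trace(freq_hz, n=8000, fs=FS, amp=1.0):
    t = np.arange(n) / fs
    return GazeTrace(t=t, x=amp * np.sin(2 * np.pi * freq_hz * t), fs_hz=fs)


def fitted_amplitude(x, freq_hz, fs=FS, skip=1000):
    """Least-squares sinusoid fit, edges excluded."""
    t = np.arange(len(x))[skip:-skip] / fs
    design = np.column_stack([np.sin(2 * np.pi * freq_hz * t),
                              np.cos(2 * np.pi * freq_hz * t)])
    coef, *_ = np.linalg.lstsq(design, x[skip:-skip], rcond=None)
    return float(np.hypot(*coef))


class TestSavgol:
    def test_degree4_through_5_points_is_identity(self):
        filt = design_savgol(5, 4, FS)
        assert np.allclose(filt.b, [0, 0, 1, 0, 0], atol=1e-10)

    def test_kernel_matches_normal_equations(self):
        """Each weight equals the centre row of the explicit least-squares
        projection built from the normal equations."""
        window, order = 11, 2
        filt = design_savgol(window, order, FS)
        half = window // 2
        t = np.arange(-half, half + 1, dtype=float)
        design = np.vander(t, order + 1, increasing=True)
        # projection of the window onto the fit, evaluated at t=0
        proj = design @ np.linalg.solve(design.T @ design, design.T)
        centre_row = proj[half]
        assert np.allclose(filt.b[::-1], centre_row, atol=1e-12)

    def test_kernel_symmetric_unit_sum(self):
        filt = design_savgol(23, 5, FS)
        assert np.allclose(filt.b, filt.b[::-1], atol=1e-12)
        assert filt.b.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            design_savgol(22, 5, FS)   # even window
        with pytest.raises(ValueError):
            design_savgol(11, 11, FS)  # order >= window

    def test_sg_equals_per_window_polynomial_fit(self):
        """Interior SG output equals the centre value of an explicit
        per-window quadratic least-squares fit."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        trace = GazeTrace.from_samples(x, FS)
        filt = design_savgol(11, 2, FS)
        out = apply_filter(filt, trace, mode="single_pass").x
        half = 5
        t = np.arange(-half, half + 1, dtype=float)
        design = np.vander(t, 3, increasing=True)
        for i in (50, 151, 248):
            coef, *_ = np.linalg.lstsq(design, x[i - half:i + half + 1],
                                       rcond=None)
            assert out[i] == pytest.approx(coef[0], abs=1e-9)


class TestButterworth:
    def test_minus3db_at_design_cutoff(self):
        filt = design_butterworth_lowpass(7, 81.0, FS)
        from gazefilt import response_direct
        resp = response_direct(filt, passes=1)
        gain_at_cutoff = np.interp(81.0, resp.freq_hz, resp.gain_db)
        assert gain_at_cutoff == pytest.approx(-3.0103, abs=0.1)

    def test_unit_dc_gain(self):
        filt = design_butterworth_lowpass(7, 81.0, FS)
        assert filt.b.sum() / filt.a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_analog_magnitude_below_40hz(self):
        """Far below Nyquist the digital response matches the analog
        closed form 1/sqrt(1+(f/81)^14) within 0.05 dB."""
        from gazefilt import response_direct
        filt = design_butterworth_lowpass(7, 81.0, FS)
        resp = response_direct(filt, passes=1)
        mask = resp.freq_hz <= 40.0
        analog_db = -10.0 * np.log10(1.0 + (resp.freq_hz[mask] / 81.0) ** 14)
        assert np.max(np.abs(resp.gain_db[mask] - analog_db)) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_butterworth_lowpass(7, 501.0, FS)


class TestFir:
    def test_unit_dc_gain(self):
        filt = design_fir_lowpass(80, 84.0, FS)
        assert filt.b.sum() == pytest.approx(1.0, abs=1e-9)

    def test_crossing_matches_dense_grid_bruteforce(self):
        """-3 dB crossing from the interpolated search agrees with a
        brute-force scan of the transfer function on a 0.01 Hz grid."""
        from gazefilt import response_direct, crossing_frequency
        from scipy import signal
        filt = design_fir_lowpass(80, 84.0, FS)
        resp = response_direct(filt, n_grid=2 ** 16, passes=2)
        interp = crossing_frequency(resp, -3.0)
        freq = np.arange(60.0, 90.0, 0.01)
        _, h = signal.freqz(filt.b, filt.a, worN=freq, fs=FS)
        db = 40.0 * np.log10(np.abs(h))
        brute = freq[int(np.argmax(db <= -3.0))]
        assert interp == pytest.approx(brute, abs=0.02)

    def test_too_few_taps_rejected(self):
        with pytest.raises(ValueError):
            design_fir_lowpass(1, 84.0, FS)


class TestTapEstimate:
    @pytest.mark.parametrize("d1,d2,fs,df,expected", [
        (0.01, 0.001, 1000.0, 40.0, 67),   # (2/3)*log10(1e4)*25 = 66.7
        (0.1, 0.1, 1000.0, 40.0, 17),      # (2/3)*log10(10)*25 = 16.7
        (0.01, 0.01, 1000.0, 1000.0, 2),   # (2/3)*3*1 = 2
    ])
    def test_formula(self, d1, d2, fs, df, expected):
        spec = TapEstimateSpec(delta1=d1, delta2=d2, fs_hz=fs,
                               transition_hz=df)
        assert estimate_fir_taps(spec) == expected

    def test_degenerate_returns_minimum(self):
        # 10*d1*d2 = 1 makes the log term vanish; floor of 2 taps applies
        spec = TapEstimateSpec(delta1=0.5, delta2=0.2, fs_hz=1000.0,
                               transition_hz=40.0)
        assert estimate_fir_taps(spec) == 2

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            TapEstimateSpec(delta1=0.0, delta2=0.1, fs_hz=1000.0,
                            transition_hz=40.0)


class TestApplyFilter:
    @pytest.mark.parametrize("name", ["sg", "iir", "fir"])
    def test_dc_invariance(self, filters, name):
        trace = GazeTrace.from_samples(np.full(4000, 3.5), FS)
        out = apply_filter(filters[name], trace)
        assert np.allclose(out.x, 3.5, atol=1e-8)

    def test_zero_phase_iir_20hz_amplitude_and_lag(self, filters):
        """A 20 Hz sinusoid through the zero-phase Butterworth keeps its
        phase (cross-correlation peak at lag 0) and comes out with
        amplitude |H(20)|^2."""
        from scipy import signal
        filt = filters["iir"]
        trace = sinusoid_trace(20.0)
        out = apply_filter(filt, trace, mode="zero_phase")
        _, h = signal.freqz(filt.b, filt.a, worN=[20.0], fs=FS)
        expected = np.abs(h[0]) ** 2
        assert fitted_amplitude(out.x, 20.0) == pytest.approx(expected,
                                                              rel=1e-4)
        inner = slice(1000, -1000)
        xc = np.correlate(out.x[inner], trace.x[inner], mode="full")
        lag = int(np.argmax(xc)) - (len(trace.x[inner]) - 1)
        assert lag == 0

    @pytest.mark.parametrize("name", ["iir", "fir"])
    @pytest.mark.parametrize("freq", [10.0, 40.0, 75.0, 90.0])
    def test_db_doubling(self, filters, name, freq):
        """Zero-phase attenuation in dB is exactly twice the single-pass
        attenuation at every probe frequency (steady state)."""
        filt = filters[name]
        trace = sinusoid_trace(freq, n=12000)
        single = fitted_amplitude(
            apply_filter(filt, trace, mode="single_pass").x, freq, skip=2000)
        double = fitted_amplitude(
            apply_filter(filt, trace, mode="zero_phase").x, freq, skip=2000)
        db_single = 20 * np.log10(single)
        db_double = 20 * np.log10(double)
        assert db_double == pytest.approx(2 * db_single, abs=0.05)

    def test_zero_phase_time_reversal_symmetry(self, filters):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(5000)
        fwd = apply_filter(filters["iir"],
                           GazeTrace.from_samples(x, FS), "zero_phase").x
        rev = apply_filter(filters["iir"],
                           GazeTrace.from_samples(x[::-1], FS),
                           "zero_phase").x[::-1]
        assert np.allclose(fwd[500:-500], rev[500:-500], atol=1e-8)

    def test_output_length_preserved(self, filters, fixation_trace):
        for name, filt in filters.items():
            out = apply_filter(filt, fixation_trace)
            assert len(out) == len(fixation_trace)

    def test_trace_too_short_for_zero_phase(self, filters):
        trace = GazeTrace.from_samples(np.zeros(100), FS)
        with pytest.raises(ValueError):
            apply_filter(filters["fir"], trace, mode="zero_phase")


class TestStability:
    def test_reference_designs_stable(self, filters):
        assert all(is_stable(f) for f in filters.values())

    def test_unstable_feedback_polynomial_detected(self):
        """A feedback root placed at modulus 1.01 must fail the unit-circle
        test; the root modulus is confirmed by brute-force root finding."""
        root = 1.01
        a = np.array([1.0, -root])  # (1 - root*z^-1)
        filt = DesignedFilter(b=np.array([1.0]), a=a,
                              spec=LowpassSpec(family="butterworth",
                                               fs_hz=FS, order=1,
                                               cutoff_hz=10.0))
        assert np.max(np.abs(np.roots(a))) == pytest.approx(1.01, abs=1e-12)
        assert not is_stable(filt)


class TestCoefficientFiles:
    def test_round_trip(self, filters, tmp_path):
        for name, filt in filters.items():
            path = tmp_path / f"{name}.txt"
            save_filter(filt, path)
            loaded = load_filter(path)
            assert loaded.spec.family == filt.spec.family
            assert np.allclose(loaded.b, filt.b, rtol=1e-5, atol=1e-12)
            assert np.allclose(loaded.a, filt.a, rtol=1e-5, atol=1e-12)
            # round-trip of the stored values is exact
            save_filter(loaded, tmp_path / f"{name}2.txt")
            again = load_filter(tmp_path / f"{name}2.txt")
            assert np.array_equal(again.b, loaded.b)
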