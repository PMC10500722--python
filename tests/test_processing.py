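"""Decay fitting, spectra, singularity picking, distance inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dressedepr as de
from dressedepr.processing import DipolarSpectrum


#: every (T µs, ξ) pair quoted for the reference compounds: phase-memory,
#: dressed-echo transverse, and spin-locked longitudinal decays
PRINTED_PAIRS = [(2.9, 5.9), (13.1, 4.6), (930.0, 2.4),
                 (3.3, 5.3), (560.0, 2.9), (14.3, 5.4),
                 (2.6, 4.9), (730.0, 2.4), (14.5, 4.4)]


class TestStretchedExponentialFit:
    @pytest.mark.parametrize("T, xi", PRINTED_PAIRS)
    def test_noiseless_round_trip_four_significant_figures(self, T, xi):
        tr = de.gen_relaxation_decay(T, xi, noise=0.0)
        fit = de.fit_stretched_exponential(tr.time, tr.amplitude)
        assert fit.converged
        assert fit.T == pytest.approx(T, rel=5e-5)
        assert fit.xi == pytest.approx(xi, rel=5e-5)

    def test_e_folding_at_T_for_any_xi(self):
        for xi in (1.0, 2.4, 5.9):
            fit = de.DecayFit(A=2.0, T=7.0, xi=xi, residual_rms=0.0,
                              covariance=np.zeros((3, 3)), converged=True)
            assert fit(7.0) == pytest.approx(2.0 / math.e, rel=1e-12)

    def test_time_scale_maps_tau1_axis_to_decay_clock(self):
        # background on the 2τ1 clock: fitting with time_scale=2 recovers
        # the T quoted on the total-evolution-time axis
        tau1 = np.linspace(0, 10, 200)
        y = np.exp(-np.power(2 * tau1 / 14.3, 5.4 / 3))
        fit = de.fit_stretched_exponential(tau1, y, time_scale=2.0)
        assert fit.T == pytest.approx(14.3, rel=1e-6)

    def test_truncated_slow_decay_is_ill_conditioned(self):
        """A 930 µs decay observed for only 40 µs leaves T very uncertain:
        wide confidence interval, scattered point estimates."""
        Ts, rel_se = [], []
        for seed in range(8):
            tr = de.gen_relaxation_decay(930.0, 2.4,
                                         grid=np.linspace(0, 40, 200),
                                         noise=0.01, seed=seed)
            fit = de.fit_stretched_exponential(tr.time, tr.amplitude)
            Ts.append(fit.T)
            rel_se.append(fit.stderr[1] / fit.T)
        assert np.median(np.abs(np.array(Ts) / 930.0 - 1.0)) < 0.5
        assert np.median(rel_se) > 0.1  # the fit itself reports the width

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            de.fit_stretched_exponential([0, 1, 2], [1, 1, 1])  # < 8 points
        t = np.linspace(0, 5, 20)
        with pytest.raises(ValueError):
            de.fit_stretched_exponential(t[::-1], np.ones(20))


class TestBackgroundDivide:
    def test_self_division_is_unity(self):
        tr = de.gen_relaxation_decay(5.0, 3.0, noise=0.0)
        fit = de.fit_stretched_exponential(tr.time, tr.amplitude)
        out = de.background_divide(tr, fit)
        assert np.allclose(out.amplitude, 1.0, atol=1e-6)

    def test_recovers_modulation_over_background(self):
        t = np.linspace(0, 8, 256)
        lam = 0.4
        mod = (1 - lam) + lam * np.cos(2 * math.pi * 0.6 * t)
        bg = np.exp(-np.power(t / 6.0, 1.5))
        fit = de.DecayFit(A=1.0, T=6.0, xi=4.5, residual_rms=0.0,
                          covariance=np.zeros((3, 3)), converged=True)
        tr = de.Trace(t, mod * bg)
        out = de.background_divide(tr, fit)
        assert np.allclose(out.amplitude, mod, atol=1e-12)

    def test_rejects_vanishing_background(self):
        t = np.linspace(0, 5, 64)
        tr = de.Trace(t, np.ones(64))
        fit = de.DecayFit(A=0.0, T=1.0, xi=3.0, residual_rms=0.0,
                          covariance=np.zeros((3, 3)), converged=True)
        with pytest.raises(ValueError):
            de.background_divide(tr, fit)


class TestDipolarSpectrum:
    def test_single_cosine_peak_position(self):
        t = np.linspace(0, 20, 512)
        tr = de.Trace(t, np.cos(2 * math.pi * 0.5 * t))
        sp = de.to_dipolar_spectrum(tr, zerofill_factor=8)
        peak = sp.frequency[np.argmax(sp.amplitude)]
        assert peak == pytest.approx(0.5, abs=2 * (sp.frequency[1] - sp.frequency[0]))

    def test_constant_trace_gives_null_spectrum(self):
        tr = de.Trace(np.linspace(0, 10, 128), np.full(128, 3.7))
        sp = de.to_dipolar_spectrum(tr)
        assert np.allclose(sp.amplitude, 0.0, atol=1e-12)

    def test_axis_spacing_and_parseval(self):
        t = np.linspace(0, 10, 256)
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, t.size)
        zf = 4
        tr = de.Trace(t, y)
        sp = de.to_dipolar_spectrum(tr, zerofill_factor=zf)
        dt = t[1] - t[0]
        assert sp.frequency[1] - sp.frequency[0] == pytest.approx(
            1.0 / (zf * 256 * dt), rel=1e-12)
        # Parseval on the full (complex) transform underlying the real part
        yc = y - y.mean()
        spec = np.fft.rfft(yc, zf * 256)
        power_f = (2 * np.sum(np.abs(spec[1:-1]) ** 2)
                   + np.abs(spec[0]) ** 2 + np.abs(spec[-1]) ** 2) / (zf * 256)
        assert power_f == pytest.approx(np.sum(yc ** 2), rel=1e-9)

    def test_rejects_nonuniform_grid(self):
        tr = de.Trace(np.array([0.0, 1.0, 3.0]), np.ones(3))
        with pytest.raises(ValueError):
            de.to_dipolar_spectrum(tr)


class TestFindSingularities:
    def _pake_spectrum(self, d=1.0):
        ps = de.pake_analytic(d, scale=0.75, smooth_sigma=0.02)
        pos = ps.frequency >= 0
        return DipolarSpectrum(frequency=ps.frequency[pos],
                               amplitude=ps.intensity[pos],
                               resolution=0.02)

    def test_three_quarter_pake_horn_and_edge(self):
        sing = de.find_singularities(self._pake_spectrum())
        assert len(sing) >= 2
        assert sing[0] == pytest.approx(0.75, abs=0.02)
        assert sing[-1] == pytest.approx(1.5, abs=0.05)

    @given(scale=st.floats(0.1, 1000.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_rescaling_invariance(self, scale):
        sp = self._pake_spectrum()
        ref = de.find_singularities(sp)
        sp2 = DipolarSpectrum(frequency=sp.frequency,
                              amplitude=sp.amplitude * scale,
                              resolution=sp.resolution)
        assert de.find_singularities(sp2) == pytest.approx(ref)

    def test_flat_spectrum_yields_nothing(self):
        sp = DipolarSpectrum(frequency=np.linspace(0, 2, 200),
                             amplitude=np.zeros(200), resolution=0.01)
        assert de.find_singularities(sp) == []

    def test_offset_broadened_ensemble_has_extra_low_singularity(self):
        """Finite-lock artifacts: an additional singularity below the
        ¾-scaled horn appears once the offset spread is on."""
        d = de.dipolar_constant_d(5.3)
        grid = de.default_tau1_grid(5.3, n_periods=8, n_points=384)
        spec = de.EnsembleSpec(r_mean=5.3, nu1=100.0,
                               offset_fwhm_nu=(16.0, 16.0),
                               n_draws=2500, seed=23)
        tr = de.ensemble_trace(spec, grid)
        sp = de.to_dipolar_spectrum(tr, window="hamming", zerofill_factor=4)
        sing = de.find_singularities(sp, prominence=0.08)
        low = [s for s in sing if 0.25 * d < s < 0.65 * d]
        assert low, f"no artifact singularity found in {sing}"


class TestDistanceInversion:
    def test_round_trips(self):
        assert de.distance_from_perp_frequency(39.03) == pytest.approx(1.000, abs=2e-3)
        assert de.distance_from_perp_frequency(0.566) == pytest.approx(4.10, abs=0.01)
        assert de.distance_from_perp_frequency(52.04, scale=1.0) == pytest.approx(
            1.000, abs=1e-3)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            de.distance_from_perp_frequency(0.0)


class TestPipeline:
    def test_synthetic_trace_to_distance(self):
        """End-to-end: generator → joint background fit → FT → horn →
        distance, on the 4.1 nm preset."""
        spec = de.SynthTraceSpec(r=4.1, lam=0.5, T=14.3, xi=5.4,
                                 noise=0.01, seed=42)
        tr = de.gen_dressed_echo_trace(spec)
        res = de.process_dressed_echo_trace(tr)
        rep = res["report"]
        assert rep["background"]["T_us"] == pytest.approx(14.3, rel=0.05)
        assert rep["background"]["xi"] == pytest.approx(5.4, rel=0.05)
        assert rep["modulation_depth"] == pytest.approx(0.5, abs=0.05)
        assert rep["r_nm"] == pytest.approx(4.1, rel=0.02)
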