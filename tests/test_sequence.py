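"""Full phase-modulated sequence propagation."""

import math
from dataclasses import replace

import numpy as np
import pytest

import dressedepr as de
from dressedepr.sequence import pm_pulse_lengths

from conftest import dominant_frequency


DRIVE = de.DriveParams(nu1=100.0, aPM=0.1)


class TestPhaseProfile:
    def test_constant_outside_pulses(self):
        assert de.phase_profile(0.3, DRIVE, None) == DRIVE.phi0
        pulse = de.PMPulse(start=1.0, duration=0.1)
        assert de.phase_profile(0.5, DRIVE, pulse) == DRIVE.phi0

    def test_peak_modulation_at_cos_zero_phase(self):
        drv = de.DriveParams(nu1=100.0, aPM=0.3, nuPM=100.0, phi0=0.0)
        pulse = de.PMPulse(start=0.0, duration=0.1, phiPM=0.0)
        assert de.phase_profile(0.0, drv, pulse) == pytest.approx(0.3)

    def test_amplitude_bound(self):
        drv = de.DriveParams(nu1=100.0, aPM=0.3, phi0=0.0)
        pulse = de.PMPulse(start=0.0, duration=0.5, phiPM=0.7)
        ts = np.linspace(0, 0.5, 400)
        phis = [de.phase_profile(t, drv, pulse) for t in ts]
        assert max(np.abs(phis)) <= 0.3 + 1e-12

    def test_zero_modulation(self):
        drv = de.DriveParams(nu1=100.0, aPM=0.0)
        pulse = de.PMPulse(start=0.0, duration=0.5)
        assert de.phase_profile(0.2, drv, pulse) == drv.phi0


class TestPropagate:
    def test_bare_pi_half_rotates_z_to_transverse(self, weak_pair):
        seq = de.SequenceSpec(t_SL=0.2, tau_SL=0.05)
        traj = de.propagate(weak_pair, seq, DRIVE)
        t_pulse = seq.t_pi2_bare_ns * 1e-3
        i = int(np.searchsorted(traj.time, t_pulse))
        assert abs(traj.Sz[i]) < 0.02      # π/2: no z left
        assert abs(traj.Sy[i]) > 1.98      # full transverse amplitude

    def test_spin_lock_holds_transverse_magnetization(self, weak_pair):
        seq = de.SequenceSpec(t_SL=1.0, tau_SL=0.05)
        traj = de.propagate(weak_pair, seq, DRIVE)
        lock = (traj.time > 0.01) & (traj.time < 1.0)
        assert np.ptp(traj.Sy[lock]) < 0.01  # locked along ±y

    def test_unitarity(self, perp_pair):
        seq = de.dressed_echo_sequence(0.5, DRIVE)
        traj = de.propagate(perp_pair, seq, DRIVE)
        assert traj.norm_drift < 1e-8

    def test_rejects_coarse_dt(self, weak_pair):
        seq = de.SequenceSpec(t_SL=0.2)
        with pytest.raises(ValueError, match="too coarse"):
            de.propagate(weak_pair, seq, DRIVE, dt=1.0 / (5 * 100))

    def test_sequence_validation(self):
        with pytest.raises(ValueError, match="pi/2"):
            de.SequenceSpec(t_SL=1.0, phi1=0.0, phiSL=0.3)
        with pytest.raises(ValueError, match="overlap"):
            de.SequenceSpec(t_SL=1.0, pm_pulses=[
                de.PMPulse(start=0.1, duration=0.2),
                de.PMPulse(start=0.2, duration=0.2)])


class TestOracleEquivalence:
    def test_full_sequence_matches_phase_inversion_simulator(self):
        """Strong-lock regime: both simulators give cos(¾ ωdd τ1)."""
        r = 6.5
        d = de.dipolar_constant_d(r)
        assert DRIVE.nu1 >= 50 * d
        for theta in (1.2, math.pi / 2):
            p = de.SpinPairParams(r=r, theta=theta, omega1_nu=DRIVE.nu1)
            wdd = de.omega_dd(r, theta)
            grid = np.linspace(0, 2 * abs(2 * math.pi / (0.75 * wdd)), 17)
            full = de.dressed_echo_trace(p, DRIVE, grid, tau_SL=0.05)
            simp = de.simulate_pair_echo(p, grid)
            rms = float(np.sqrt(np.mean((full.amplitude - simp.amplitude) ** 2)))
            assert rms < 0.03

    def test_uncoupled_pair_gives_flat_trace(self, weak_pair):
        grid = np.linspace(0, 1.0, 6)
        tr = de.dressed_echo_trace(weak_pair, DRIVE, grid)
        assert np.allclose(tr.amplitude, 1.0, atol=1e-3)


class TestEchoPosition:
    def test_refocusing_optimum_at_symmetric_delays(self):
        """Under an ω1 spread the dressed echo forms at τ2 = τ1 (edge-to-
        edge delays; pulse centres symmetric about the π pulse)."""
        tau1 = 0.6
        nu1s = np.linspace(96, 104, 9)
        w = np.exp(-0.5 * ((nu1s - 100) / 2.5) ** 2)
        tau2s = tau1 + np.linspace(-0.06, 0.06, 13)
        prof = []
        for tau2 in tau2s:
            tot = 0j
            for nu1, wi in zip(nu1s, w):
                drv = de.DriveParams(nu1=float(nu1), aPM=0.1, nuPM=100.0)
                p = de.SpinPairParams(r=8.0, theta=de.MAGIC_ANGLE,
                                      omega1_nu=float(nu1))
                seq = de.dressed_echo_sequence(tau1, drv, tau2=float(tau2),
                                               tau_SL=0.05, t_SL=2.5)
                tot += wi * de.propagate(p, seq, drv, record=False).echo
            prof.append(abs(tot))
        step = tau2s[1] - tau2s[0]
        assert abs(tau2s[int(np.argmax(prof))] - tau1) <= step + 1e-12


class TestDressedNutation:
    def test_nominal_nutation_frequency_small_apm(self, weak_pair):
        grid = np.linspace(0, 400, 81)
        tr = de.dressed_nutation(weak_pair, DRIVE, grid)
        f = dominant_frequency(tr.time, tr.amplitude)
        assert f == pytest.approx(DRIVE.nu1 * DRIVE.aPM / 2, rel=0.05)

    def test_zero_apm_is_flat(self, weak_pair):
        drv = de.DriveParams(nu1=100.0, aPM=0.0)
        tr = de.dressed_nutation(weak_pair, drv, np.linspace(0, 200, 11))
        assert np.ptp(tr.amplitude) < 1e-6

    def test_large_apm_pi_pulse_bracket(self, weak_pair):
        """At aPM = 0.3 the π time stays near nominal (33.3 ns) but the
        inversion is incomplete — the counter-rotating PM component at
        work."""
        drv = de.DriveParams(nu1=100.0, aPM=0.3)
        grid = np.linspace(20, 50, 31)
        tr = de.dressed_nutation(weak_pair, drv, grid)
        i = int(np.argmin(tr.amplitude))
        t_pi_ns = tr.time[i] * 1e3
        assert 30.0 <= t_pi_ns <= 45.0
        assert tr.amplitude[i] > -1.0 + 0.01  # inversion not complete

    def test_dressed_offset_adds_in_quadrature(self, weak_pair):
        """Detuning ωPM from ω1 by δ acts as a dressed-spin offset δ."""
        def nutation_freq(nuPM):
            drv = de.DriveParams(nu1=100.0, aPM=0.1, nuPM=nuPM)
            g = np.linspace(0, 600, 121)
            tr = de.dressed_nutation(weak_pair, drv, g)
            return dominant_frequency(tr.time, tr.amplitude)

        f0 = nutation_freq(100.0)
        f3 = nutation_freq(97.0)
        assert f3 == pytest.approx(math.hypot(f0, 3.0), rel=0.05)


class TestPhaseCycle:
    def test_single_step_equals_propagate(self, perp_pair):
        seq = de.dressed_echo_sequence(0.3, DRIVE)
        direct = de.propagate(perp_pair, seq, DRIVE, record=False).echo
        cycled = de.run_phase_cycle(perp_pair, seq, DRIVE,
                                    cycle=[de.CycleStep()])
        assert cycled == pytest.approx(direct, rel=1e-12)

    def test_no_coupling_flat_under_default_cycle(self, weak_pair):
        cyc = de.default_phase_cycle()
        assert len(cyc) == 16
        grid = np.linspace(0, 0.8, 4)
        tr = de.dressed_echo_trace(weak_pair, DRIVE, grid, cycle=cyc[:4])
        assert np.allclose(tr.amplitude, 1.0, atol=1e-3)

    def test_suppresses_pm_bypass_signal(self):
        """Magnetization passing miscalibrated PM pulses unrotated is
        insensitive to τ2; the cycle must remove it ≥ 10×."""
        nu1s = np.linspace(96, 104, 5)
        w = np.exp(-0.5 * ((nu1s - 100) / 2.5) ** 2)
        w /= w.sum()
        tau1, tau2 = 0.8, 0.92
        cyc = de.default_phase_cycle()
        tot_u, tot_c = 0j, 0j
        for nu1, wi in zip(nu1s, w):
            drv = de.DriveParams(nu1=float(nu1), aPM=0.1, nuPM=100.0)
            p = de.SpinPairParams(r=8.0, theta=de.MAGIC_ANGLE,
                                  omega1_nu=float(nu1))
            seq = de.dressed_echo_sequence(tau1, drv, tau2=tau2,
                                           tau_SL=0.05, t_SL=3.0)
            for pp in seq.pm_pulses:
                pp.duration *= 0.7  # miscalibrated flips leave bypass signal
            tot_u += wi * de.propagate(p, seq, drv, record=False).echo
            tot_c += wi * de.run_phase_cycle(p, seq, drv, cycle=cyc)
        assert abs(tot_u) / max(abs(tot_c), 1e-12) >= 10.0

    def test_rejects_empty_or_null_cycle(self, perp_pair):
        seq = de.dressed_echo_sequence(0.2, DRIVE)
        with pytest.raises(ValueError):
            de.run_phase_cycle(perp_pair, seq, DRIVE, cycle=[])
        with pytest.raises(ValueError):
            de.run_phase_cycle(perp_pair, seq, DRIVE,
                               cycle=[de.CycleStep(receiver=0.0)])


class TestHyperfineDecoupling:
    def test_nothing_to_decouple(self):
        assert de.hyperfine_decoupling_demo(0.0, 14.8, 100.0) == 1.0
        assert de.hyperfine_decoupling_demo(5.0, 14.8, 0.0) == pytest.approx(1.0)

    def test_attenuation_improves_with_drive(self):
        a100 = de.hyperfine_decoupling_demo(5.0, 14.8, 100.0)
        a50 = de.hyperfine_decoupling_demo(5.0, 14.8, 50.0)
        a25 = de.hyperfine_decoupling_demo(5.0, 14.8, 25.0)
        assert a100 < a50 < a25 < 1.0
        assert a50 >= 2.0 * a100  # roughly (A/2ν1)²: halved drive, ≥2× residual
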