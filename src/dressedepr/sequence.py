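"""Exact rotating-frame propagation of the phase-modulated spin-lock sequence.

The sequence is: bare π/2 pulse (phase φ1) → spin lock (phase φSL,
|φSL−φ1| = π/2) carrying up to three phase-modulation (PM) pulses
(π/2 – τ1 – π – τ2 – π/2, phases φ2–φ4) → delay τSL → bare π pulse →
delay τSL → echo read-out.  During a PM pulse the microwave phase is

    φmw(t) = φSL + aPM · cos(ωPM t + φPM),

and the full cos φ / sin φ drive terms are kept — no small-aPM
truncation, so Bloch–Siegert-type deviations of the dressed nutation are
reproduced.  Propagation is piecewise-constant with a matrix exponential
per step (exact within the sampling criterion); segments with constant
Hamiltonian are diagonalized once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spins import SpinPairParams, build_two_spin_hamiltonian, two_spin_ops
from .trace import Trace

__all__ = [
    "DriveParams",
    "PMPulse",
    "SequenceSpec",
    "CycleStep",
    "StateTrajectory",
    "phase_profile",
    "pm_pulse_lengths",
    "dressed_echo_sequence",
    "propagate",
    "echo_amplitude",
    "dressed_echo_trace",
    "dressed_nutation",
    "run_phase_cycle",
    "default_phase_cycle",
    "hyperfine_decoupling_demo",
]

TWO_PI = 2.0 * math.pi


@dataclass
class DriveParams:
    """Microwave drive: Rabi frequency and phase-modulation parameters.

    ``nu1`` and ``nuPM`` in MHz, ``phi0`` in rad, ``aPM`` in rad
    (dimensionless modulation index).  ``aPM << 1`` is deliberately *not*
    enforced: breakdown of the rotating-wave approximation for the dressed
    spins at large aPM is part of what this simulator probes.
    """

    nu1: float
    aPM: float = 0.1
    nuPM: float | None = None  # defaults to nu1 (on-resonance dressed drive)
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.nu1 < 0 or self.aPM < 0:
            raise ValueError("nu1 and aPM must be >= 0")
        if self.nuPM is None:
            self.nuPM = self.nu1


@dataclass
class PMPulse:
    """One phase-modulation pulse within the lock (times in µs, local to lock)."""

    start: float
    duration: float
    phiPM: float = 0.0
    aPM_override: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("PM pulse duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class CycleStep:
    """Phase increments (rad) and complex receiver weight for one cycle step."""

    dphi1: float = 0.0
    dphiSL: float = 0.0
    dphi2: float = 0.0
    dphi3: float = 0.0
    dphi4: float = 0.0
    receiver: complex = 1.0 + 0.0j


@dataclass
class SequenceSpec:
    """Timing skeleton of the dressed-echo experiment.

    Bare pulse lengths are in ns (converted internally); the lock duration
    ``t_SL``, read-out delay ``tau_SL`` and PM pulse times are in µs.
    """

    t_pi2_bare_ns: float = 2.5
    phi1: float = 0.0
    t_SL: float = 1.0
    phiSL: float = math.pi / 2
    pm_pulses: list[PMPulse] = field(default_factory=list)
    tau_SL: float = 0.2
    t_pi_bare_ns: float = 5.0
    phase_cycle: list[CycleStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_SL <= 0 or self.tau_SL < 0:
            raise ValueError("t_SL must be > 0 and tau_SL >= 0")
        dphi = abs(self.phiSL - self.phi1) % TWO_PI
        if not (math.isclose(dphi, math.pi / 2, abs_tol=1e-9)
                or math.isclose(dphi, 3 * math.pi / 2, abs_tol=1e-9)):
            raise ValueError("|phiSL - phi1| must be pi/2 (lock along the coherence)")
        pulses = sorted(self.pm_pulses, key=lambda p: p.start)
        for a, b in zip(pulses, pulses[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError("PM pulses overlap")
        for p in pulses:
            if p.start < -1e-12 or p.end > self.t_SL + 1e-9:
                raise ValueError("PM pulse outside the spin lock")
        self.pm_pulses = pulses


def phase_profile(t: float, drive: DriveParams, pulse: PMPulse | None) -> float:
    """Microwave phase at lock-local time ``t`` (µs).

    Returns φ0 outside PM pulses and φ0 + aPM·cos(ωPM t + φPM) inside;
    note the modulation clock runs on lock time, so the dressed-pulse
    phase φPM is defined relative to the lock start.
    """
    if pulse is None or not (pulse.start <= t <= pulse.end):
        return drive.phi0
    a = pulse.aPM_override if pulse.aPM_override is not None else drive.aPM
    return drive.phi0 + a * math.cos(TWO_PI * drive.nuPM * t + pulse.phiPM)


def pm_pulse_lengths(drive: DriveParams) -> tuple[float, float]:
    """(t_π/2, t_π) of dressed pulses in µs from the first-order nutation rate.

    The dressed nutation frequency is ν1·aPM/2, hence
    t_π/2 = 1/(4·ν1·aPM/2) = 1/(2·ν1·aPM).
    """
    if drive.nu1 <= 0 or drive.aPM <= 0:
        raise ValueError("need nu1 > 0 and aPM > 0 for PM pulses")
    t_pi2 = 1.0 / (2.0 * drive.nu1 * drive.aPM)
    return t_pi2, 2.0 * t_pi2


def dressed_echo_sequence(tau1: float, drive: DriveParams,
                          tau0: float = 0.05, tau2: float | None = None,
                          tau_SL: float = 0.2, lock_tail: float = 0.02,
                          t_pi2_bare_ns: float | None = None,
                          phi1: float = 0.0,
                          phases: tuple[float, float, float] = (0.0, 0.0, 0.0),
                          t_SL: float | None = None,
                          ) -> SequenceSpec:
    """Build the three-PM-pulse echo sequence for a given delay τ1 (µs).

    Delays are measured between pulse edges.  Since t_π = 2·t_π/2, the
    pulse centres are symmetric about the refocusing π pulse for
    τ2 = τ1, which is where the dressed echo forms under an ω1 spread;
    that is the default unless ``tau2`` is given explicitly.  Bare pulse
    lengths default to the π/2 time at the drive's own Rabi frequency.
    ``phases`` are (φ2, φ3, φ4).

    For a τ1 series pass a fixed ``t_SL`` covering the longest delay —
    the experiment runs at constant lock length, and a lock that grows
    with τ1 imprints the ω1-fast phase of residual (uncycled) dressed
    coherence onto the trace.
    """
    if tau1 < 0:
        raise ValueError("tau1 must be >= 0")
    if t_pi2_bare_ns is None:
        t_pi2_bare_ns = 1e3 / (4.0 * drive.nu1)
    t_pi2, t_pi = pm_pulse_lengths(drive)
    if tau2 is None:
        tau2 = tau1
    s1 = tau0
    s2 = s1 + t_pi2 + tau1
    s3 = s2 + t_pi + tau2
    if t_SL is None:
        t_SL = s3 + t_pi2 + lock_tail
    elif t_SL < s3 + t_pi2:
        raise ValueError("t_SL does not cover the PM pulses")
    phi2, phi3, phi4 = phases
    return SequenceSpec(
        t_pi2_bare_ns=t_pi2_bare_ns,
        phi1=phi1,
        t_SL=t_SL,
        phiSL=phi1 + math.pi / 2,
        pm_pulses=[
            PMPulse(start=s1, duration=t_pi2, phiPM=phi2),
            PMPulse(start=s2, duration=t_pi, phiPM=phi3),
            PMPulse(start=s3, duration=t_pi2, phiPM=phi4),
        ],
        tau_SL=tau_SL,
        t_pi_bare_ns=2.0 * t_pi2_bare_ns,
    )


@dataclass
class StateTrajectory:
    """Time axis (µs), observable series, and the final complex echo."""

    time: np.ndarray
    Sz: np.ndarray
    Sx: np.ndarray
    Sy: np.ndarray
    echo: complex
    norm_drift: float

    def observable(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _default_dt(params: SpinPairParams, drive: DriveParams) -> float:
    fmax = max(drive.nu1, drive.nuPM or 0.0, abs(params.offset1_nu),
               abs(params.offset2_nu), 1.0)
    return 1.0 / (40.0 * fmax)


def _check_dt(dt: float, params: SpinPairParams, drive: DriveParams) -> None:
    fmax = max(drive.nu1, drive.nuPM or 0.0)
    if fmax > 0 and dt > 1.0 / (20.0 * fmax) + 1e-15:
        raise ValueError(
            f"dt = {dt:g} us too coarse for max frequency {fmax:g} MHz; "
            "need dt <= 1/(20*max(nu1, nuPM)) to avoid aliasing the phase "
            "modulation")


def _segments(seq: SequenceSpec):
    """Yield (duration_us, kind, payload) covering the whole sequence.

    kinds: 'pulse' / 'lock' (constant drive at the payload phase), 'free'
    (no drive), 'pm' (payload = the PMPulse; phase varies within).
    """
    t_pi2 = seq.t_pi2_bare_ns * 1e-3
    t_pi = seq.t_pi_bare_ns * 1e-3
    yield (t_pi2, "pulse", seq.phi1)
    # the spin lock, split at PM pulse boundaries
    cursor = 0.0
    for p in seq.pm_pulses:
        if p.start > cursor + 1e-12:
            yield (p.start - cursor, "lock", seq.phiSL)
        yield (p.duration, "pm", p)
        cursor = p.end
    if seq.t_SL > cursor + 1e-12:
        yield (seq.t_SL - cursor, "lock", seq.phiSL)
    yield (seq.tau_SL, "free", None)
    yield (t_pi, "pulse", seq.phi1)
    yield (seq.tau_SL, "free", None)


def propagate(params: SpinPairParams, seq: SequenceSpec, drive: DriveParams,
              dt: float | None = None, record: bool = True) -> StateTrajectory:
    """Propagate the density operator through the full sequence.

    The initial state is both spins polarized along +z (the traceless part
    of thermal equilibrium; overall scaling is irrelevant to normalized
    traces).  Constant segments use one eigendecomposition; PM segments
    are stepped at ``dt`` with the phase sampled at each step midpoint.
    """
    if dt is None:
        dt = _default_dt(params, drive)
    _check_dt(dt, params, drive)
    ops = two_spin_ops()
    rho = np.array(ops.Sz, dtype=complex)
    norm0 = np.linalg.norm(rho)
    times: list[float] = []
    obs: list[tuple[float, float, float]] = []
    t_abs = 0.0
    lock_clock = 0.0  # lock-local time driving the PM oscillator

    def rec(t: float, r: np.ndarray) -> None:
        if record:
            times.append(t)
            obs.append((
                float(np.trace(r @ ops.Sz).real),
                float(np.trace(r @ ops.Sx).real),
                float(np.trace(r @ ops.Sy).real),
            ))

    rec(0.0, rho)
    for duration, kind, payload in _segments(seq):
        if duration <= 0:
            continue
        n = max(1, int(math.ceil(duration / dt)))
        if kind != "pm" and not record:
            n = 1  # constant Hamiltonian: one exact step
        h = duration / n
        if kind != "pm":
            if kind in ("pulse", "lock"):
                phase = float(payload)
                H = build_two_spin_hamiltonian(params, drive.nu1, phase)
            else:
                H = build_two_spin_hamiltonian(params, 0.0, 0.0)
            evals, V = np.linalg.eigh(H)
            U = V @ np.diag(np.exp(-1j * evals * h)) @ V.conj().T
            for _ in range(n):
                rho = U @ rho @ U.conj().T
                t_abs += h
                rec(t_abs, rho)
        else:  # PM pulse: time-dependent phase, batched over the steps
            pulse: PMPulse = payload
            t_mid = lock_clock + (np.arange(n) + 0.5) * h
            a = pulse.aPM_override if pulse.aPM_override is not None else drive.aPM
            phases = seq.phiSL + a * np.cos(TWO_PI * drive.nuPM * t_mid
                                            + pulse.phiPM)
            H0 = build_two_spin_hamiltonian(params, 0.0, 0.0)
            w1 = TWO_PI * drive.nu1
            Hb = (H0[None, :, :]
                  + w1 * np.cos(phases)[:, None, None] * ops.Sx[None, :, :]
                  + w1 * np.sin(phases)[:, None, None] * ops.Sy[None, :, :])
            evals, V = np.linalg.eigh(Hb)
            Us = np.einsum("nij,nj,nkj->nik", V, np.exp(-1j * evals * h),
                           V.conj())
            for k in range(n):
                U = Us[k]
                rho = U @ rho @ U.conj().T
                t_abs += h
                rec(t_abs, rho)
        # the PM oscillator clock runs on lock-local time
        if kind in ("pm", "lock"):
            lock_clock += duration
    echo = complex(np.trace(rho @ ops.Sx).real + 1j * np.trace(rho @ ops.Sy).real)
    drift = abs(np.linalg.norm(rho) - norm0) / norm0
    if record:
        t_arr = np.asarray(times)
        o = np.asarray(obs)
        return StateTrajectory(t_arr, o[:, 0], o[:, 1], o[:, 2], echo, drift)
    return StateTrajectory(np.array([t_abs]), np.array([np.trace(rho @ ops.Sz).real]),
                           np.array([np.trace(rho @ ops.Sx).real]),
                           np.array([np.trace(rho @ ops.Sy).real]), echo, drift)


def echo_amplitude(traj: StateTrajectory, phi_ref: float) -> float:
    """Signed echo amplitude: projection of the complex echo on axis φ_ref."""
    return float((np.exp(-1j * phi_ref) * traj.echo).real)


def run_phase_cycle(params: SpinPairParams, seq: SequenceSpec,
                    drive: DriveParams, cycle: list[CycleStep] | None = None,
                    dt: float | None = None) -> complex:
    """Receiver-weighted mean echo over a phase cycle.

    Phase increments are applied to the bare π/2 / lock phases (φ1, φSL)
    and the three PM-pulse phases (φ2–φ4); each step's complex echo is
    multiplied by the receiver weight and the results averaged.
    """
    steps = cycle if cycle is not None else (seq.phase_cycle or [CycleStep()])
    if not steps:
        raise ValueError("phase cycle table is empty")
    norm = sum(abs(s.receiver) for s in steps)
    if norm == 0:
        raise ValueError("receiver weights sum to zero normalization")
    total = 0.0 + 0.0j
    for s in steps:
        pulses = [replace(p) for p in seq.pm_pulses]
        for p, dphi in zip(pulses, (s.dphi2, s.dphi3, s.dphi4)):
            p.phiPM = p.phiPM + dphi
        seq_s = replace(seq, phi1=seq.phi1 + s.dphi1,
                        phiSL=seq.phiSL + s.dphiSL, pm_pulses=pulses)
        traj = propagate(params, seq_s, drive, dt=dt, record=False)
        total += s.receiver * traj.echo
    return total / len(steps)


def default_phase_cycle() -> list[CycleStep]:
    """16-step cycle: ±π inversions of φ2 and φ4 nested with a 4-step
    rotation of the bare-pulse/lock phases (receiver counter-rotated).

    Suppresses magnetization that bypasses the PM π/2 pulses (it does not
    change sign under the φ2/φ4 inversions) and crossing echoes with the
    wrong coherence pathway under the 4-step rotation.
    """
    steps = []
    for dphi2, s2 in ((0.0, 1.0), (math.pi, -1.0)):
        for dphi4, s4 in ((0.0, 1.0), (math.pi, -1.0)):
            for k in range(4):
                chi = k * math.pi / 2
                steps.append(CycleStep(
                    dphi1=chi, dphiSL=chi, dphi2=dphi2, dphi4=dphi4,
                    receiver=s2 * s4 * complex(math.cos(chi), -math.sin(chi))))
    return steps


def dressed_echo_trace(params: SpinPairParams, drive: DriveParams,
                       tau1_grid, tau0: float = 0.05, tau_SL: float = 0.2,
                       dt: float | None = None,
                       cycle: list[CycleStep] | None = None) -> Trace:
    """Signed echo amplitude versus τ1 (normalized at τ1 = 0).

    One full-sequence propagation per grid point, with the read-out echo
    projected on the lock axis and normalized by the τ1 = 0 value.
    """
    grid = np.asarray(tau1_grid, dtype=float)
    if grid.size == 0 or grid[0] != 0:
        raise ValueError("tau1_grid must start at 0")
    # constant lock length, sized for the longest delay (as in the experiment)
    t_pi2, t_pi = pm_pulse_lengths(drive)
    t_SL = tau0 + 3 * t_pi2 + t_pi + 2 * float(grid[-1]) + 0.02
    amps = []
    for tau1 in grid:
        seq = dressed_echo_sequence(float(tau1), drive, tau0=tau0,
                                    tau_SL=tau_SL, t_SL=t_SL)
        if cycle is None:
            traj = propagate(params, seq, drive, dt=dt, record=False)
            e = traj.echo
        else:
            e = run_phase_cycle(params, seq, drive, cycle=cycle, dt=dt)
        amps.append((np.exp(-1j * seq.phiSL) * e).real)
    amps = np.asarray(amps)
    if amps[0] == 0:
        raise RuntimeError("zero echo at tau1 = 0; cannot normalize")
    return Trace(grid, amps / amps[0], {
        "kind": "dressed_echo_full_sequence", "time_axis": "tau1",
        "r_nm": params.r, "theta_rad": params.theta,
        "nu1_MHz": drive.nu1, "aPM": drive.aPM,
    })


def dressed_nutation(params: SpinPairParams, drive: DriveParams,
                     pm_length_grid_ns, tau0: float = 0.05,
                     tau_SL: float = 0.2, lock_tail: float = 0.05,
                     dt: float | None = None) -> Trace:
    """Echo amplitude versus the length of a single PM pulse.

    The dominant oscillation frequency is the dressed nutation rate
    ν1·aPM/2 (first order); at large aPM the counter-rotating PM component
    lengthens the effective π time and superimposes Bloch–Siegert-type
    wiggles.  The returned time axis is in µs.
    """
    grid_ns = np.asarray(pm_length_grid_ns, dtype=float)
    if np.any(grid_ns < 0):
        raise ValueError("PM pulse lengths must be >= 0")
    amps = []
    for tp_ns in np.concatenate([[0.0], grid_ns]):  # leading 0: reference
        tp = tp_ns * 1e-3
        if tp == 0 or drive.aPM == 0:
            pulses = []
            t_SL = tau0 + tp + lock_tail
        else:
            pulses = [PMPulse(start=tau0, duration=tp, phiPM=0.0)]
            t_SL = tau0 + tp + lock_tail
        t_bare = 1e3 / (4.0 * drive.nu1)
        seq = SequenceSpec(t_SL=t_SL, phi1=0.0, phiSL=math.pi / 2,
                           pm_pulses=pulses, tau_SL=tau_SL,
                           t_pi2_bare_ns=t_bare, t_pi_bare_ns=2 * t_bare)
        traj = propagate(params, seq, drive, dt=dt, record=False)
        amps.append((np.exp(-1j * seq.phiSL) * traj.echo).real)
    amps = np.asarray(amps)
    scale = amps[0] if amps[0] != 0 else 1.0  # the zero-length reference
    amps = amps[1:]
    return Trace(grid_ns * 1e-3, amps / scale, {
        "kind": "pm_nutation", "time_axis": "pm_pulse_length",
        "nu1_MHz": drive.nu1, "aPM": drive.aPM,
        "nominal_nutation_MHz": drive.nu1 * drive.aPM / 2.0,
    })


def hyperfine_decoupling_demo(A_nu: float, nuI_nu: float, nu1: float,
                              duration: float = 2.0,
                              n_samples: int = 4001) -> float:
    """Attenuation of hyperfine-driven electron modulation under a lock.

    Electron–nucleus system H0 = 2π·A·SzIz + 2π·νI·Iz with the electron
    prepared along its (effective) quantization axis x.  Returns the ratio
    of the peak-to-peak modulation of the locked component with the drive
    2π·ν1·Sx on versus off; 1 when there is nothing to decouple (A = 0 or
    ν1 = 0) and falling roughly as (A/2ν1)² deep in the decoupled regime.
    """
    ops = two_spin_ops()  # spin 1 = electron, spin 2 = nucleus
    H0 = TWO_PI * A_nu * ops.S1z @ ops.S2z + TWO_PI * nuI_nu * ops.S2z
    rho0 = np.array(ops.S1x, dtype=complex)
    fmax = max(abs(A_nu), abs(nuI_nu), nu1, 1.0)
    ts = np.linspace(0.0, duration, n_samples)

    def depth(H: np.ndarray) -> float:
        evals, V = np.linalg.eigh(H)
        rd = V.conj().T @ rho0 @ V
        Od = V.conj().T @ ops.S1x @ V
        ph = np.exp(-1j * np.outer(ts, evals))
        # <S1x>(t) = sum_{ij} rd_ij e^{-i(l_i-l_j)t} Od_ji
        sig = np.einsum("ti,ij,tj,ji->t", ph, rd, ph.conj(), Od).real
        return float(sig.max() - sig.min())

    d_free = depth(H0)
    if d_free < 1e-12:
        return 1.0
    d_lock = depth(H0 + TWO_PI * nu1 * ops.S1x)
    return d_lock / d_free
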