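"""Seeded generators emulating experimental dressed-echo data.

A measured dressed-echo trace is modelled as

    V(τ1) = [(1 − λ) + λ·K(τ1)] · exp(−(2τ1/T)^(ξ/3)) + ε(τ1)

where K is the powder dipolar modulation kernel (closed-form quadrature
by default, or a Monte-Carlo ensemble trace for artifact-bearing
fixtures), λ is the modulation depth, the stretched exponential is the
phenomenological background on the total-evolution-time clock 2τ1, and
ε is i.i.d. Gaussian noise.  Relaxation decays are generated from the
same stretched-exponential model directly.  Everything is deterministic
under a fixed seed, so fixtures regenerate bit-identically.

The generators reproduce only the *statistical structure* of real
traces — powder modulation at ¾ of the dipolar frequency, partial
modulation depth, a fast stretched-exponential background, additive
noise — not microscopic decoherence, ESEEM, or instantaneous diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locksim import EnsembleSpec, default_tau1_grid, ensemble_trace
from .nutating import powder_closed_form_trace
from .trace import Trace

__all__ = [
    "SynthTraceSpec",
    "gen_dressed_echo_trace",
    "gen_relaxation_decay",
    "RELAXATION_PRESETS",
    "DRESSED_ECHO_PRESETS",
    "generate_preset",
]


@dataclass
class SynthTraceSpec:
    """Recipe for one synthetic dressed-echo trace.

    ``r`` (nm) or an ``ensemble`` for the modulation kernel; modulation
    depth ``lam`` in [0, 1]; background (T in µs on the 2τ1 clock, ξ);
    ``noise`` as a fraction of the initial amplitude; τ1 grid and seed.
    """

    r: float = 4.1
    lam: float = 0.5
    T: float = 14.3
    xi: float = 5.4
    noise: float = 0.01
    tau1_grid: np.ndarray | None = None
    seed: int = 0
    ensemble: EnsembleSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("modulation depth lam must lie in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.T <= 0 or self.xi <= 0:
            raise ValueError("background T and xi must be > 0")


def gen_dressed_echo_trace(spec: SynthTraceSpec) -> Trace:
    """Synthetic dressed-echo modulation trace per the model above.

    With λ = 0 the trace is a pure stretched-exponential decay; with
    λ = 1, no noise and no background it equals the modulation kernel.
    """
    grid = spec.tau1_grid if spec.tau1_grid is not None \
        else default_tau1_grid(spec.r)
    grid = np.asarray(grid, dtype=float)
    if spec.ensemble is not None:
        kernel = ensemble_trace(spec.ensemble, grid, r_fixed=spec.r).amplitude
    else:
        kernel = powder_closed_form_trace(spec.r, grid).amplitude
    background = np.exp(-np.power(2.0 * grid / spec.T, spec.xi / 3.0))
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise, grid.size) if spec.noise > 0 else 0.0
    amp = ((1.0 - spec.lam) + spec.lam * kernel) * background + noise
    return Trace(grid, amp, {
        "kind": "synthetic_dressed_echo", "time_axis": "tau1",
        "r_nm": spec.r, "lambda": spec.lam,
        "background": {"T_us": spec.T, "xi": spec.xi, "time_scale": 2},
        "noise_sigma": spec.noise, "seed": spec.seed,
        "kernel": "ensemble" if spec.ensemble is not None else "closed_form",
    })


def gen_relaxation_decay(T: float, xi: float, grid=None, noise: float = 0.0,
                         seed: int = 0, A: float = 1.0) -> Trace:
    """A·exp(−(t/T)^(ξ/3)) + seeded Gaussian noise on the given t grid (µs)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    if grid is None:
        grid = np.linspace(0.0, 3.0 * T, 256)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    amp = A * np.exp(-np.power(grid / T, xi / 3.0))
    if noise > 0:
        amp = amp + rng.normal(0.0, noise * A, grid.size)
    return Trace(grid, amp, {
        "kind": "synthetic_relaxation_decay", "time_axis": "t",
        "T_us": T, "xi": xi, "noise_sigma": noise, "seed": seed, "A": A,
    })


#: (label, T µs, ξ) triples of the reference relaxation curves: two-pulse
#: phase-memory decay, dressed-echo transverse decay, and spin-locked
#: longitudinal decay of the mono-radical reference sample.
RELAXATION_PRESETS: dict[str, list[tuple[str, float, float]]] = {
    "mono-trityl": [("Tm", 2.9, 5.9), ("T2rho", 13.1, 4.6), ("T1rho", 930.0, 2.4)],
    "ruler-4p1nm": [("Tm", 3.3, 5.3), ("T1rho", 560.0, 2.9)],
    "ruler-5p3nm": [("Tm", 2.6, 4.9), ("T1rho", 730.0, 2.4)],
}

#: dressed-echo trace presets for the two bis-trityl rulers: distance,
#: background (T2ρ, ξ) and a mid-range modulation depth.
DRESSED_ECHO_PRESETS: dict[str, SynthTraceSpec] = {
    "ruler-4p1nm": SynthTraceSpec(r=4.1, lam=0.5, T=14.3, xi=5.4, noise=0.01),
    "ruler-5p3nm": SynthTraceSpec(r=5.3, lam=0.5, T=14.5, xi=4.4, noise=0.01),
}


def generate_preset(name: str, seed: int = 0) -> dict[str, Trace]:
    """Named fixture sets; returns {curve label: Trace}.

    Relaxation presets emit one noiseless-model-plus-noise decay per
    printed (T, ξ) pair; dressed-echo presets emit one modulation trace.
    """
    out: dict[str, Trace] = {}
    if name in RELAXATION_PRESETS:
        for i, (label, T, xi) in enumerate(RELAXATION_PRESETS[name]):
            out[label] = gen_relaxation_decay(T, xi, noise=0.01, seed=seed + i)
    if name in DRESSED_ECHO_PRESETS:
        from dataclasses import replace
        out["dressed_echo"] = gen_dressed_echo_trace(
            replace(DRESSED_ECHO_PRESETS[name], seed=seed))
    if not out:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(set(RELAXATION_PRESETS) | set(DRESSED_ECHO_PRESETS))}")
    return out
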