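# dressedepr

Simulation and analysis toolkit for **dressed-spin pulse EPR distance
measurement**: dipolar spectroscopy carried out *during* a strong
microwave spin lock, with "pulses" applied to the microwave-dressed
spins by sinusoidal phase modulation (PM) of the carrier.

## The problem

Pulsed dipolar EPR (DEER, DQC, SIFTER, RIDME) extracts nanometre
distances between spin labels from the r⁻³ dipole–dipole coupling, but
the usable evolution window is capped by the electron phase-memory time
Tm — typically a few µs at 50 K, dominated by the nuclear spin bath.
Driving the electrons continuously decouples them from the nuclei
(hyperfine decoupling), so coherence of the *dressed* spins survives on
the much longer rotating-frame timescales T2ρ ≫ Tm, while the
electron–electron coupling stays active.  For narrow-line labels such as
trityl radicals, where one microwave frequency excites the whole
spectrum, this promises substantially longer measurable distances.  The
toolkit is aimed at magnetic-resonance methodologists who want to
simulate such sequences, understand their artifacts, and process the
resulting echo-modulation traces into distances.

## The model

In the nutating frame of a lock with Rabi frequency ω1 along x′:

* resonance offsets `Ω Sz` average to zero (first order),
* secular hyperfine couplings average to zero — hyperfine decoupling,
* isotropic exchange `J S1·S2` is invariant,
* the dipolar coupling survives, scaled by **−1/2** and tilted onto the
  lock axis.

Equal dressed frequencies make the two spins magnetically equivalent, so
the strong-coupling factor **3/2** applies on top: a dressed echo
generated by a PM π/2–τ1–π–τ2–π/2 block refocuses drive inhomogeneity
but keeps the dipolar coupling, and its amplitude oscillates as

    V(τ1) = cos(¾ · ωdd · τ1),   ωdd = 2π d (1 − 3 cos²θ),
    d = (μ0/4π) μB² g² / (2π ħ r³) = 52.04 MHz · (nm/r)³,

producing a ¾-scaled powder (Pake) pattern in frozen solution: a horn at
¾·d and an edge at twice that.  When the Rabi frequency is *not* far
above the offset spread, pairs with unequal dressed frequencies drop the
3/2 factor and extra low-frequency singularities appear — the package's
Monte-Carlo ensembles reproduce and quantify these finite-Rabi
artifacts.

Modules: `spins` (operators, Hamiltonians, constants), `nutating`
(average-Hamiltonian oracles, closed forms, Pake lineshapes), `sequence`
(exact propagation of the full PM sequence, phase cycling, PM nutation,
hyperfine-decoupling demo), `locksim` (phase-inversion shortcut
simulator + Monte-Carlo powder/offset ensembles), `processing`
(stretched-exponential fits, background division, dipolar spectra,
singularity picking, distance inversion), `synth` (seeded synthetic-data
generators), `trace`/`config`/`cli` (file formats, run configs, command
line).  See `docs/methods.md` for conventions and numerical choices.

## Worked example

Generate a synthetic 4.1 nm ruler trace (modulation depth 0.5, T2ρ-like
background 14.3 µs with ξ = 5.4, SNR 100) and push it through the full
pipeline:

```python
import dressedepr as de

spec  = de.SynthTraceSpec(r=4.1, lam=0.5, T=14.3, xi=5.4, noise=0.01, seed=7)
trace = de.gen_dressed_echo_trace(spec)
report = de.process_dressed_echo_trace(trace)["report"]
print(report)
```

prints (abridged):

```
background:        T = 14.297 µs, ξ = 5.474   (true: 14.3, 5.4)
modulation_depth:  0.501                      (true: 0.5)
singularities_MHz: [0.151, 0.545, 0.676, 1.170]
nu_perp_MHz:       0.545
r_nm:              4.153                      (true: 4.1)
```

The horn at 0.545 MHz is the ¾-scaled perpendicular dipolar frequency
(¾·d(4.1 nm) = 0.566 MHz, pulled ~1 % low by the finite trace length);
the outermost entry is the parallel edge near twice the horn; inverting
the horn with the ¾ scale returns the distance to ~1.3 %.

The same pipeline is available from the shell:

```sh
dressed-epr synth --preset ruler-4p1nm --seed 7 --out out/
dressed-epr process out/ruler-4p1nm_dressed_echo.dat --out out/
dressed-epr simulate --panel b --r 5.3 --n-draws 10000 --seed 1 --out out/
dressed-epr aht-check       # prints {"offset": 0.0, "dipolar": -0.5, "drive": 1.0, "J": 1.0}
```

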