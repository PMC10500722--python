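# Methods

`dressedepr` simulates and analyses nanometre distance measurement
between electron spins whose dipolar evolution takes place *during* a
strong microwave spin lock, with pulses applied to the microwave-dressed
spins through sinusoidal phase modulation (PM) of the carrier.  This note
records the models, conventions, numerical choices and limitations.

## Physical model

Two electron spins S = 1/2 in the microwave rotating frame:

    H' = Ω1 S1z + Ω2 S2z
         + ωdd(r, θ) (S1z S2z − ½(S1x S2x + S1y S2y))
         + J S1·S2
         + ω1 [cos φmw(t) (S1x+S2x) + sin φmw(t) (S1y+S2y)]

with the secular point-dipole coupling

    ωdd = 2π d (1 − 3cos²θ),   d = (1/2π)(μ0/4π)(μB² g1 g2 / ħ) r⁻³.

For free-electron g factors, d = 52.04 MHz·(nm/r)³; this anchor is
computed from CODATA constants, never hard-coded.  g anisotropy is
neglected (appropriate for trityl-type radicals with near-isotropic
g ≈ 2.003; the anchor value is insensitive to the difference at four
significant figures).  The magic angle θ = arccos(1/√3) nulls ωdd.

**Units.** All interface frequencies are ordinary frequencies in MHz and
all times in µs; internally every Hamiltonian is an angular frequency in
rad/µs.  Because 1 MHz = 1 µs⁻¹ the conversion is a bare 2π, which keeps
the mixed frequency/angular-frequency bookkeeping auditable.

## Nutating-frame averaging (`nutating`)

Under a strong lock ω1 along x, first-order average Hamiltonian theory in
the frame nutating at ω1 predicts: offsets average to zero; a secular
hyperfine coupling averages to zero when only the electron is driven
(hyperfine decoupling — the mechanism that extends dressed-spin coherence
far beyond the bare phase-memory time); isotropic exchange is invariant;
and the dipolar coupling survives, scaled by −1/2 with its unique axis
tilted onto the lock axis.  The package computes these averages *numerically*:
(1/T)∫ U†HU dt over one nutation period by the midpoint rule, which is
spectrally exact for the trigonometric integrands here once the node
count (default 256) exceeds the harmonic content.  One mechanism
validates all four statements uniformly and also serves the
electron–nucleus demonstration system.

Because the two dressed spins share one quantization axis they are
magnetically equivalent; the strong-coupling (flip-flop) regime
contributes a further factor 3/2.  The dressed-echo modulation therefore
runs at (1/2)·(3/2) = **3/4 of the bare dipolar frequency**; both factors
are exposed separately (`SPIN_LOCK_SCALE`, `STRONG_COUPLING_SCALE`).

The closed-form echo signal is cos(¾ ωdd τ1) after total evolution 2τ1.
The sign of the detected oscillation depends on the back-rotation phase
convention; only magnitude spectra are compared to data.

## Trace axis convention

Dressed-echo modulation traces carry **τ1** (one inter-pulse delay) as
their time axis — the axis of the echo-evolution figures — so the powder
horn of a 4.1 nm pair appears at ¾·d = 0.566 MHz.  The phenomenological
decay, however, runs on the *total* evolution time 2τ1: stretched-
exponential fits take `time_scale=2` so the fitted T lands on the T2ρ
scale (≈ 13–15 µs for the systems emulated here).  This single convention
reproduces both the quoted horn frequencies and the quoted relaxation
constants simultaneously.

## Full sequence simulator (`sequence`)

The experiment is: bare π/2 (phase φ1) → lock (φSL, |φSL−φ1| = π/2) with
PM pulses π/2–τ1–π–τ2–π/2 (phases φ2–φ4, modulation
φmw = φSL + aPM cos(ωPM t + φPM), clock referenced to the lock start) →
τSL → bare π → τSL → echo.  Propagation is piecewise-constant with one
matrix exponential (via eigendecomposition of the 4×4 Hamiltonian) per
step, keeping the full cos φ/sin φ drive — no small-aPM truncation — so
Bloch–Siegert-type deviations of the dressed nutation are physical
output, not error.  Constant segments are advanced in one exact step.
The step criterion dt ≤ 1/(20·max(ν1, νPM)) is enforced; the default is
1/40.  Unitarity is conserved to ~1e−13 per sequence.

Design choices:

* **Initial state** — both spins polarized along +z, amplitude 1 per
  spin; thermal scaling is irrelevant to normalized traces.
* **Read-out** — complex ⟨Sx⟩ + i⟨Sy⟩ at the nominal echo time after the
  τSL–π–τSL block, projected onto the lock axis for signed traces; a
  point sample at the echo maximum stands in for the experimental echo
  integral.
* **Bare pulses** — constant-amplitude rectangles at the lock's ν1, π/2
  length 1/(4ν1) by default (narrow-line systems are excited uniformly).
* **PM pulse lengths** — from the first-order dressed nutation rate
  ν1·aPM/2: t_π/2 = 1/(2 ν1 aPM).  At aPM = 0.3 the simulator finds the
  deepest inversion at ≈ 32.5 ns versus the nominal 33.3 ns, with
  incomplete inversion: the counter-rotating PM component shifts the
  dressed resonance and *raises* the effective nutation rate.  Reported
  experimental π times of ~40 ns are therefore mostly instrumental.
* **Delay convention** — inter-pulse delays are edge-to-edge.  Since
  t_π = 2 t_π/2, pulse centres are symmetric about the refocusing pulse
  at τ2 = τ1, which is where the dressed echo forms under an ω1 spread
  (verified to one 5 ns scan step); published echo-position rules that
  add t_π/2 encode the same placement under a different delay reference.
* **Constant lock length** — a τ1 series is simulated at fixed t_SL
  sized for the longest delay.  A lock that grows with τ1 imprints the
  ω1-fast phase of residual dressed coherence onto the trace as
  pseudo-random jitter; the experiment avoids this the same way.
* **Phase cycle** — the default 16-step table nests ±π inversions of φ2
  and φ4 (receiver ∓) with a 4-step rotation of φ1/φSL
  (receiver counter-rotated).  It suppresses magnetization that bypasses
  the PM pulses (≥ 10× in the regression test) without prescribing any
  particular hardware convention; the table is fully user-overridable.

Not modelled: resonator transfer functions, amplifier noise, stochastic
relaxation superoperators (decay enters only through the phenomenological
background of the synthetic-data module).

## Simplified simulator and ensembles (`locksim`)

The dressed π pulse is emulated by inverting the drive sign at the
midpoint of the lock: ν1(t) = +ν1 for t < τ1, −ν1 for τ1 ≤ t < 2τ1, with
⟨S1z+S2z⟩ read at 2τ1.  Each half has a constant Hamiltonian, so one
eigendecomposition per half is reused across the whole τ1 grid — the
cost per Monte-Carlo draw is O(grid) on 4×4 matrices.  The simulator is
validated to 3e−13 against independent step-wise `expm` propagation, and
against the full PM-sequence simulator to < 3 % RMS in the strong-lock
regime (ν1 ≥ 50 d; at stronger coupling the dipolar phase accumulated
*during* the PM pulses, which the shortcut omits by construction,
becomes visible first).

Monte-Carlo ensembles draw Ω1, Ω2 (Gaussian, FWHM/√(8 ln 2) standard
deviation, zero mean — on-resonance irradiation), r (Gaussian, zero width
by default: fixed ruler length) and θ (P(θ) = sinθ on [0, π/2]) as
independent variables; the independence assumption is a simplification —
rigid linkers correlate label orientations in reality.  A deterministic
Gauss–Legendre quadrature in cosθ (`powder_trace_quadrature`) provides
the powder average without sampling noise.

**Finite-Rabi artifacts.**  With an offset spread switched on, spin pairs
whose members acquire different dressed frequencies
(ωeff,i = √(ω1² + Ωi²)) lose the strong-coupling 3/2 factor: the dressed
flip-flop truncates and the surviving Ising part modulates at ½·ωdd
instead of ¾·ωdd.  Single-pair scans show the transition cleanly
(0.750 d ↔ 0.500 d); powder/offset ensembles at 5.3 nm, FWHM 16 MHz,
ν1 = 100 MHz show the artifact band peaking at ≈ 0.47–0.50·d (window-
dependent) below the main horn at 0.75·d.  Published readings place these
artifacts "around 3/8·d" (or "around 3/8·ν⊥" ≈ 0.28·d, two mutually
inconsistent statements); this package reports the measured position and
the weak-coupling mechanism behind it.  The artifact *trends* are
unambiguous and reproduced: intensity falls when the offset FWHM drops
16 → 8 MHz and again when ν1 rises 100 → 200 → 400 MHz.

## Processing pipeline (`processing`)

* **Stretched exponential** f(t) = A·exp(−(t/T)^(ξ/3)) — the ξ/3
  convention means fitted ξ of 2.4–5.9 correspond to conventional stretch
  exponents 0.8–2.0.  Deterministic initialization (A = y(0), T = the
  interpolated e-folding time, ξ = 3), bounds T > 0, ξ ∈ [0.3, 12];
  non-convergence and bound-hits are flagged, never silent.  Covariance
  from the Gauss–Newton approximation; a 930 µs decay truncated at 40 µs
  correctly reports a relative standard error on T above 30 % — the
  ill-conditioning is a feature of the measurement, and the fit says so.
* **Background of modulated traces** — with partial modulation depth
  λ < 1 a plain stretched-exponential fit of the whole trace is dragged
  tens of percent off the true envelope by the slowly decaying powder
  kernel tail (and a tail-only fit remains biased at the 20 % level).
  The pipeline therefore refines the background *jointly* with the
  modulation: V(τ1) = A[(1−λ) + λK_ν⊥(τ1)]·exp(−(2τ1/T)^(ξ/3)), where
  K_ν⊥ is the ¾-scaled powder kernel parameterized only by its horn
  frequency, seeded by a whole-trace fit plus a provisional horn pick.
  This recovers T and ξ to better than 2 % at SNR 100 and yields λ and
  ν⊥ as by-products.  The plain whole-trace fit remains available
  (`modulation_fit=False`).
* **Spectra** — mean subtraction, optional half-Hamming apodization
  (taper on the tail only, preserving the t = 0 cosine reference),
  zero-filling (default 4×), real part of the FFT; times in µs give MHz
  axes directly.
* **Singularity picking** — local maxima above a relative prominence
  threshold, with parabolic sub-bin refinement; sub-resolution peaks
  (baseline ripple) are discarded.  The outer (parallel) edge is located
  at the steepest *logarithmic* descent beyond the horn: the edge drops
  to zero (unbounded relative change) while the horn flank only drops to
  the shoulder plateau, which makes the criterion resolution-robust.
  The default shoulder floor is 5 % of the horn amplitude — against
  resolution-limited horns the plateau sits near 7 %, far below the 20 %
  a naive reading of idealized lineshapes would suggest.
* **Distance** — r = (scale·d(1 nm)/ν⊥)^(1/3) with scale = ¾ and the
  1 nm prefactor computed from constants.

Known biases: the horn position is pulled ~1 % below ¾·d at the default
6-period trace length by the asymmetric lineshape convolved with the
window (shrinking like 1/length); the end-to-end distance error at SNR
100 is ≈ 1.5 %, within the 2 % target.

## Synthetic data (`synth`)

V(τ1) = [(1−λ) + λK(τ1)]·exp(−(2τ1/T)^(ξ/3)) + ε, with K the closed-form
powder kernel (or an ensemble trace for artifact-bearing fixtures) and ε
i.i.d. Gaussian.  Defaults emulate the measured systems: rulers at 4.1
and 5.3 nm with backgrounds (14.3 µs, ξ = 5.4) and (14.5 µs, ξ = 4.4);
reference relaxation presets (2.9, 5.9), (13.1, 4.6), (930, 2.4) µs for
the mono-radical and the corresponding ruler values.  The true
experimental modulation depth and SNR are not published; λ defaults to
0.5 (depth below unity is reported without a number) and noise to 1 % —
both always explicit in fixture metadata.  Generators are bit-reproducible
under fixed seeds.  What passing tests show is that the *pipeline* is
correct and well-conditioned under this statistical structure; they do
not validate microscopic decoherence physics (ESEEM, instantaneous
diffusion, intermolecular backgrounds), which enter only through the
phenomenological envelope.

## Problem sizes

Defaults used by the test-suite and the acceptance script: 512–4096-point
τ1 grids (6–40 oscillation periods), 201-node powder quadrature, 10⁴
Monte-Carlo draws for ensemble spectra, 16–25 full-sequence propagations
per oracle trace.  These sizes put every quantity well inside its quoted
tolerance while keeping a full run in tens of seconds on one core; all
are arguments, not constants.
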