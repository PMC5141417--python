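# Methods

`spasim` predicts the specific power absorption (SPA, also called SLP) of
single-domain magnetic nanoparticles under an alternating magnetic field,
with the supporting analyses used when designing hyperthermia agents for
intracellular conditions. This note documents the models, the parameter
conventions, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Physical model

### Two-level Stoner–Wohlfarth dynamic hysteresis (`spasim.hysteresis`)

Each particle is a coherent uniaxial macrospin. With the moment angle θ and
easy-axis angle ψ measured from the field axis, the reduced energy is

    e(θ) = sin²(θ − ψ) − 2·h_app(t)·cosθ − 2·h_bias·cos(θ − ψ)

in units of K_eff·V, with all fields divided by the anisotropy field
H_A = 2K_eff/(μ₀M_S). **Normalization:** the zero-field barrier is exactly
1 (= K_eff·V in physical units) and the aligned-case barriers are the
closed forms (1∓h)²; the switching field obeys the Stoner–Wohlfarth
astroid h_sw(ψ) = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}. Both closed forms are
pinned by tests against the numerical landscape solver.

At every step of the discretized sinusoidal sweep H(t) = H₀·sin(2πft) the
two minima, the lowest saddle and the moment projections cosθ at the minima
are located on a periodic grid with three-point parabolic refinement. The
well populations n₁, n₂ follow the two-level master equation with
Arrhenius escape rates

    1/τ_i = (1/(2τ₀)) · exp(−ΔE_i / k_BT),

integrated exactly (exponential relaxation toward the instantaneous
Boltzmann equilibrium) over each step, rates held constant within a step.
**Rate convention.** The ½ prefactor makes the total zero-field relaxation
rate of the magnetization, 1/τ₁ + 1/τ₂, equal to the Néel rate
(1/τ₀)·exp(−K_effV/k_BT) used everywhere else in the package; with a bare
1/τ₀ per well the simulator and the linear-response module would disagree
by up to a factor 2 in the relaxation time, which the cross-validation test
(simulator vs. linear response at small field, below) would expose. When a
minimum has vanished (h beyond the astroid) its barrier is zero and its
moment projection is redefined to the surviving minimum, so the moment
rolls over deterministically and the residual population drains within a
few attempt times.

The recorded magnetization blends the superparamagnetic and blocked limits
through the probability of equilibration within one step,
L = 1 − exp(−Δt/τ_total), 1/τ_total = 1/τ₁ + 1/τ₂:

    M = L·⟨M⟩_SP + (1 − L)·(n₁M₁ + n₂M₂),

where ⟨M⟩_SP is the two-state Boltzmann average of the minima projections
and M_i = M_S·cosθ_i. Within-well fluctuations are neglected (the moment
sits at the minimum); the reversible intra-well tilt is included because
the minima positions are recomputed each step. Because Δt is small, L is
essentially a smooth bridge to equilibrium in regions of fast relaxation
and the master equation carries the physics; this keeps the model exactly
consistent with linear response at small fields.

SPA is the enclosed loop area times μ₀f,

    SPA = μ₀ · f · (−∮ M dH)   [W per kg of magnetic material],

evaluated by periodic trapezoidal integration over the last full cycle.
The first cycle is always discarded as a transient; cycles are appended
(up to a cap of 12) until consecutive areas agree to 1%, else a warning is
raised.

### Ensembles

Monte-Carlo ensembles draw, per particle,

* a core diameter from a Gaussian with the TEM moments, truncated at
  ±3 s.d. and at a 5 nm floor (a moment-matched lognormal is selectable);
* an easy-axis orientation uniform on the sphere (easy axes are **static**:
  Brownian rotation is deliberately excluded, matching the agglomerated,
  rotation-blocked intracellular regime — predictions for free colloids
  should add the Brownian channel through the linear-response module and
  are then approximate);
* a static dipolar bias field collinear with the easy axis, magnitude
  uniform in [coupling_min, coupling_max]·H₀ (default 2–5%), random sign.

The ensemble SPA is the **mass-weighted** average of per-particle SPA
(weights ∝ d³): SPA is power per unit mass, so the ensemble value is total
power over total mass. The standard error uses the matching weighted-
variance estimator. `spa_vs_field` reuses one particle draw across the
whole amplitude grid (common random numbers; the bias scales with H₀ as
the mean-field picture prescribes), which makes SPA(H₀) smooth enough for
power-law fitting at moderate ensemble sizes.

Setting the temperature to zero runs the athermal (deterministic
Stoner–Wohlfarth) limit: transitions occur only when a well vanishes. This
limit reproduces the textbook aligned square loop (coercivity H_A, area
4M_S·H_A) and the classic random-orientation coercivity ≈ 0.48·H_A.

### Dipolar interactions (`spasim.dipolar`)

Intracellular agglomerates are idealized as hexagonal-close-packed
clusters of spheres with a configurable surface gap (default 5 nm, the
space left after the polymer coating is lost on uptake). For the central
particle the point-dipole pair-energy sum over the 12 nearest neighbours
vanishes identically when moments are equal and parallel — the shell's
direction tensor Σr̂r̂ᵀ equals 4·I — so only packing distortions
(positional jitter, neighbour-size dispersity) produce a net magnetostatic
energy. The simulator therefore receives the interaction as the static
per-particle mean-field bias described above rather than an explicit
lattice sum; the bias is not made self-consistent with the instantaneous
magnetization. Point dipoles are used throughout (no finite-sphere
multipoles, no chain geometries, no inter-core exchange).

### Relaxation screening (`spasim.relaxation`) and linear response (`spasim.lrt`)

Néel time τ_N = τ₀·exp(K_effV/k_BT) (zero-field Arrhenius; the
field-dependent barrier belongs to the simulator), Brownian time
τ_B = 3ηV_H/k_BT, parallel-rate combination 1/τ = 1/τ_N + 1/τ_B. The
regime classifier uses Ω = K_eff/η with **mandatory** user-supplied
cutoffs (Ω_low, Ω_high) — there is no consensus value to default to.

The linear-response SPA uses the Rosensweig form
SPA = μ₀πχ₀H₀²f·[2πfτ/(1+(2πfτ)²)]/ρ with the Langevin initial
susceptibility χ₀ = μ₀M_S²V/(3k_BT) (not a chord susceptibility). It warns
above H₀/H_A = 0.2 and refuses above 1. The simulator and this closed form
agree within a few percent for H₀/H_A ≤ 0.05 (tested at the 15% level),
which is the strongest internal consistency check in the package.

### Calorimetry (`spasim.calorimetry`) and regressions (`spasim.fitting`)

SPA extraction from heating traces uses the quasi-adiabatic initial-slope
method: an OLS slope over the first 30 s after the instrument dead time,
times (m_l·c_l + m_np·c_np)/m_np. A sliding-window maximum-slope variant
is available behind a flag; the fixed window is the default because the
two coincide for the convex-from-above traces the method assumes. Repeat
measurements can be reported both as mean-of-fits and fit-of-mean.

The SPA(H₀) power law SPA = Φ·H₀^λ is fitted by nonlinear least squares
initialized from the log–log OLS line (λ is scale-equivariant under
rescaling of H₀, which is tested). The FMR anisotropy line is an OLS of
H_res against cos²θ; the anisotropy-field estimate is the slope magnitude
(identity-slope convention — no Smit–Beljers lineshape analysis).

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| density | 5180 | kg/m³ | bulk magnetite; config-overridable |
| τ₀ | 1e-9 | s | upper end of the 1e-10–1e-9 s attempt-time range for magnetite |
| K_eff ↔ H_A | K = μ₀M_S H_A/2 | — | uniaxial single-domain identity; either may be given |
| gap | 5e-9 | m | bare-core spacing after coating loss |
| coupling | 0.02–0.05 of H₀ | — | calibrated mean-field interaction range for dense agglomerates |
| steps/cycle | 2000 | — | loop areas change <0.5% vs 4000 at the working points |
| cycles | 3 (first discarded) | — | steady state verified by the 1% area check |
| φ grid | 720 points + parabolic refinement | — | barrier accuracy ≲1e-8 of K_effV |
| c_l, c_np | 4186, 670 | J/(kg·K) | water and magnetite specific heats |
| slope window | 30 | s | initial-slope convention |

Internal units are strict SI; kA/m, Oe and mT appear only at I/O
boundaries (`convert_field`, config keys with unit suffixes).

## Synthetic-data generators

`calorimetry.generate_heating_curve` solves the linear heating ODE with an
optional Newton-cooling loss term and additive Gaussian noise; zero loss
and zero noise reproduce the adiabatic assumption exactly, closing the
loop with the slope estimator to 1e-10 relative. It does not emulate probe
lag, field inhomogeneity or convection. `fitting.generate_spa_curve` adds
multiplicative log-normal noise (measured SPA scatter grows with SPA);
`fitting.generate_fmr_scan` adds additive noise to an ideal uniaxial
cos²θ line. Passing tests on these fixtures therefore demonstrates
estimator correctness, not robustness to instrument systematics.

## Reference working points and a known limitation

The test suite and `scripts/acceptance.py` exercise two published
magnetite colloid parameter sets: d = 25 ± 5 nm, M_S = 51 Am²/kg,
H_A = 34.5 kA/m, and d = 32 ± 6 nm, M_S = 54 Am²/kg, H_A = 55 kA/m, both
at T = 300 K, f = 560 kHz, H₀ up to 24 kA/m, with 2–5% dipolar coupling.
Problem sizes are 500 particles for the single-point SPA and 300 particles
per amplitude for SPA(H₀) sweeps; at these sizes the ensemble standard
error is a few percent and results are seed-reproducible.

At these working points the model, as specified above, predicts a
substantially **larger** in-vitro SPA (≈ 800 W/g at 24 kA/m for the first
parameter set, as computed by the acceptance suite) and a different
field-exponent structure (the first set's SPA(H₀) saturates within the
12–24 kA/m window; the second set's grows much more steeply) than the
calorimetric values reported for these colloids inside cells
(≈ 220 W/g, λ ≈ 4). The gap is structural: at 560 kHz the Arrhenius
criterion makes a median 25 nm particle switch at 0.2–0.5·H_A with a wide
loop, and no admissible parameter choice (number- vs mass-weighting,
τ₀ ∈ [1e-10, 1e-9] s, mono- vs polydisperse, finer discretization — all
re-checked) brings the two-level prediction down to the measured scale.
Reproducing the measured scale would require a different
superparamagnetic/blocked blending than the per-step construction used
here, but period-scale blending breaks the exact small-field agreement
with linear response that this package treats as non-negotiable. Users
should treat absolute SPA predictions in the strongly nonlinear regime
(H₀ ≳ 0.5·H_A) as upper bounds; trends in f, H₀, size and viscosity, the
linear-response regime, and all supporting analyses are quantitative.

## Other known limitations

* Coherent rotation only: no Landau–Lifshitz–Gilbert dynamics, curling or
  internal modes (relevant to FMR at ≳250 kA/m bias fields).
* The mean-field bias is static per particle over a loop; no N-body
  dipolar dynamics or self-consistency.
* Polydispersity enters only the simulator; χ₀ in the linear-response
  module is monodisperse.
* Per-cell SPA (μW/cell) is out of scope: it requires the cellular iron
  load, which is an experimental input.
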