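# Methods

This note records the models implemented in `mfrelease`, the conventions
chosen where the underlying formalism leaves freedom, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Classical release models

All five models act on a `ReleaseCurve` (times in hours, cumulative release
as fraction or percent). Internal computation runs on the fraction scale;
rate constants are reported on the curve's declared unit scale, except the
Korsmeyer–Peppas constants, which are defined on the fraction scale.

Conventions that needed a decision:

- **First order.** The printed law `log₁₀Q = k·t/2.303` has no intercept,
  but an intercept-free log regression through cumulative data is ill-posed
  as t → 0. The fit therefore includes an intercept log₁₀Q₀ and reports
  k = slope × ln 10 (the customary 2.303 is rounded ln 10; the exact value
  is used internally so that generate → fit round trips are exact). The
  through-origin slope is additionally reported as `k_through_origin`,
  since published tables rarely state which convention they used.
- **Hixson–Crowell.** The cube-root law `W₀^⅓ − W_t^⅓ = k·t` gives a
  positive k for release, yet results tables in this field often report the
  signed OLS slope of the opposite orientation (W_t^⅓ − W₀^⅓ vs t), which
  is negative. The fit reports both: `k_hc` (signed slope, default "table"
  orientation) and `k_release` (positive, printed-law orientation). W₀
  defaults to the full declared scale (100 on percent curves) unless the
  loaded dose is supplied. Prediction clamps the remaining amount at zero
  and warns when the dose is exhausted.
- **R².** Linearized fits report R² on the linearized scale (that is what
  straight-line release plots show); nonlinear fits report R² on the
  original scale. The `method` field labels which one applies.
- **Windows.** Stage windows are closed intervals; boundary points belong
  to both adjoining windows, and overlapping windows are allowed with a
  warning. Defaults are the two-stage protocol 1–8 h and 24–120 h.
- **Korsmeyer–Peppas scope.** No ≤60%-release restriction is imposed by
  default; callers who want the conventional restriction can pass a window
  that enforces it.

Nonlinear fits (`fit_nonlinear`) run unweighted least squares on the
original scale, initialized from the linearized fit; on noiseless
model-true data the two routes agree to floating precision, on
heteroscedastic data they differ and both are reported.

## Multifractal release function

Synchronized multifractal dynamics reduce to a diffusion equation
∂ρ/∂t = σ∂²ρ/∂x² for the states density. For a plane sheet of thickness δ,
uniform initial density and perfect-sink walls, the released fraction is a
function of τ = σt/δ² alone. Three evaluations are shipped:

- `release_fraction_exact` — the eigenfunction series
  f(τ) = 1 − Σ₈/((2m+1)²π²)·exp(−(2m+1)²π²τ). This is the variant
  validated against the independent PDE solver, and it matches the
  classical short-time erfc/ierfc expansion
  f = 4√τ·[π^(−1/2) + 2Σ(−1)ⁿ ierfc(n/(2√τ))] to machine precision
  (asserted in the tests).
- `release_fraction_paper` — a frequently printed erfc variant,
  f = 2√τ·[π^(−1/2) + Σ(−1)ⁿ erfc(n/(2√τ))], kept exactly as printed for
  auditability. It is *not* equivalent to the exact solution: it replaces
  ierfc by erfc and halves the prefactor, so it runs ≈ factor 2 low at
  small τ and deviates by up to ≈ 0.59 (at τ ≈ 0.59) over τ ∈ [1e−4, 2].
  That deviation is computed by the test suite and committed as a fixture
  (`tests/fixtures/paper_variant_audit.json`), not hidden; fitting with
  `variant="paper"` is available but `exact` is the default everywhere.
- `release_fraction_early` — the early-time law f = C√τ with
  C = 4/√π ≈ 2.2568, obtained by regressing the exact solution on √τ over
  τ ∈ [1e−8, 1e−6] (`calibrate_early_constant` reproduces the derivation).
  It stays within 1% of the exact solution for τ ≤ 1e−3.

Series truncation: terms are summed up to `n_terms` (default 200 for the
eigenseries — the first omitted exponential is < 1e−15 for τ ≳ 2e−4 — and
50 for the erfc variant); both functions can return the magnitude of the
first omitted term as an explicit tail bound.

`fit_release` estimates the reduced rate θ = σ/δ² in 1/h by least squares
of M_∞·f(θt) against the observed fractions, with the plateau M_∞ free by
default (hydrogel formulations commonly stop well below full release;
fixing M_∞ = 1 would bias θ). Initialization comes from the early-time
law. A window containing only the plateau leaves θ unidentifiable and is
flagged in the result's warnings rather than silently returning a number.

**Scale-resolution mapping.** The multifractal degree obeys
σ = λ·(dt)^(2/f(α)−1). This exponent reading is the unique one under which
f(α) = 2 (ordinary diffusion on Peano-type motion curves) gives σ = λ at
every scale resolution, which is the formalism's own consistency limit; the
convention is centralized in `sigma_from_dimension` and inverted in
`fractal_dimension_from_sigma` (f(α) = 2/(1 + ln(σ/λ)/ln dt)). λ and dt
are not measurable from a release curve, so fractalization-degree reporting
requires user-supplied (λ, dt) and is labeled convention-dependent.
Degenerate combinations (dt = 1 with σ ≠ λ, vanishing exponent
denominator, non-positive results) raise domain errors with explanations.

## Finite-difference oracle

`pde_oracle` solves the sheet problem by a method deliberately independent
of the series: Crank–Nicolson in time (unconditionally stable, second
order) on the unit interval, second-order central differences in space,
Dirichlet walls, with tau = θt so one solve serves every θ. Three
numerical details matter:

- **Rannacher start.** The first two steps are taken as pairs of
  backward-Euler half-steps to damp the high modes excited by the
  discontinuous initial data.
- **Adaptive steps.** dτ ≤ 0.004·τ (geometric growth from 1e−9) resolves
  the √τ transient with ~5000 cheap banded solves out to τ = 2.
- **Jump-corrected initial projection.** The uniform initial density is
  incompatible with the walls; projecting it naively onto the nodes leaves
  an O(h²/τ) error in the released fraction whose constant comes from the
  k⁴/24 term of the lattice dispersion cos k = 1 − k²/2 + k⁴/24 − ….
  Augmenting the wall-adjacent nodes by 1/24 of the jump height cancels
  that leading term (1/24 was verified to be the universal zero of the
  leading error across n_x = 101…401). Released mass uses composite
  Simpson quadrature. With these choices the solver at n_x = 401 agrees
  with the 200-term eigenseries to 7e−7 over τ ∈ [1e−4, 2], while the
  scheme remains plainly second order (measured order 2.12 on a
  τ ∈ [1e−3, 1] refinement ladder, where the smooth-solution error
  dominates; at very small τ the jump correction superconverges and the
  apparent order is higher).
- Values requested below the grid's resolvable time (τ ≲ h²) reflect the
  representation of the initial jump, not the physics; they are accurate
  only to ~1e−3 there.

A nonzero surface density ρ₁ is handled by solving for ρ − ρ₁ and scaling
the released fraction by (ρ₀ − ρ₁)/ρ₀. Norm growth at any step raises a
stability error naming the violated contract (none is expected — the
scheme is unconditionally stable — but the check guards against future
edits).

## Multifractal hydrodynamics

The 1-D hydrodynamic system couples momentum
∂ₜV_D + V_D∂ₓV_D = −∂ₓQ and continuity ∂ₜρ + ∂ₓ(ρV_D) = 0 through the
quantum-like specific potential Q built from √ρ. For a free Gaussian
packet (initial width α, velocity V₀) the closed-form fields are

    s²(t) = α² + (σ/α)²t²
    V_D = (V₀α² + (σ/α)²xt)/s²
    ρ   = π^(−1/2) s^(−1) exp(−(x − V₀t)²/s²)
    V_F = σ(x − V₀t)/s²

**Potential prefactor.** With Q = −c·σ²·(∂²√ρ)/√ρ, symbolic substitution
of the packet into the momentum equation leaves a residual proportional to
(2c − 1): the packet is an exact solution only for c = 1/2. The package
therefore defines Q = −(σ²/2)(∂²√ρ)/√ρ (`QPOT_COEF`). This corresponds to
identifying the scale-relativity diffusion coefficient D with σ/2 (the
familiar ħ/m ↔ 2D correspondence); prefactors such as 2σ² that circulate
in the literature are inconsistent with the printed packet solution, as
the residual verification would immediately show. The width parameter
enters as (σ/α)²t², the unique reading that keeps ρ unit-normalized for
all t (verified by quadrature to 1e−10 and required by the conservation
law).

Nondimensionalization (ξ = x/(V₀τ₀), η = t/τ₀, μ = στ₀/α², φ = α/(V₀τ₀))
gives V = (1 + μ²ξη)/(1 + μ²η²) and U = μ(ξ − η)/(1 + μ²η²), whence
U/V = μ(ξ − η)/(1 + μ²ξη) — a homography in η at fixed ξ.
`check_homographic` certifies this numerically by a total-least-squares
Möbius fit (SVD nullspace of [η, 1, −rη, −r]); a constant ratio (μ = 0)
leaves the homography underdetermined and is flagged degenerate rather
than fitted. `synchronization_locus` returns the ξ(η) curve of constant
U/V (default the V = −U locus) on which d(U/V)/dη vanishes — the
dynamical-simultaneity condition that motivates the diffusion reduction.

`hydro_residuals` discretizes both conservation laws with second-order
central differences (one-sided at boundaries, `edge_order=2`) and reports
max-norms over the region where ρ exceeds 1e−3 of its peak (the potential
divides by √ρ and is meaningless in the far tails). For the analytic
packet both norms fall at second order under joint (x, t) refinement; a
deliberately perturbed density is caught by the continuity residual.

## Synthetic data

`synthetic_data` emulates the in-vitro protocol the fits assume:

- **Two-stage structure.** Ground truth is any classical model or a
  multifractal variant; with multiple stages, each stage runs on its own
  clock, is zeroed at its start and shifted to the previous terminal
  value, and stays active until the next stage begins — the curve is
  continuous and nondecreasing by construction (which is why no
  "discontinuous joint" error can occur).
- **Plateau.** Default terminal release 0.70 — the characteristic terminal
  fraction of crosslinked-hydrogel formulations. For multifractal truths
  the plateau is the M_∞ multiplier; for kinetics truths it optionally
  rescales the final value (and is disabled, `plateau=None`, in
  self-consistency tests, which require the curve to equal the truth model
  exactly).
- **Noise.** Multiplicative Gaussian on the release values (UV–Vis
  quantification errors are relative); default relative SD 5% in the
  recovery studies. An additive option exists. Values are clipped at zero.
- **Sampling schedule.** {1, 2, 3, 4, 6, 8} h through the burst, then
  daily to 240 h (16 points) — a declared convention spanning an 8 h burst
  and a 10-day experiment; exact experimental timepoints are rarely
  published.
- **Aliquot accounting.** Withdrawing an aliquot v_a from a vessel of
  volume V and replacing it with fresh buffer removes analyte; the
  cumulative amount at step j is M_j = c_j·V + v_a·Σ_{i<j} c_i. The
  generator simulates the measured concentrations with the inverse map and
  the correction restores the truth exactly (round trip to 1e−10).

What passing these tests shows: the estimators are unbiased and precise
under the stated noise model, the stage structure and the sampling design.
What they do not show: robustness to drifting plateaus, autocorrelated or
heteroscedastic-beyond-multiplicative noise, drug degradation, matrix
erosion, or model misspecification between the classical and multifractal
families — real release curves contain all of these.

## Verification studies and their sizes

The acceptance script and test suite use: 50 log-spaced τ ∈ [1e−4, 2] for
series/solver agreement (n_x = 401, 200 eigenterms); 200 replicate seeds
for the θ recovery study (|bias| ≤ 2%, RMSE ≤ 10% at 5% noise on the
default 16-point schedule); 4-level refinement ladders for both the
FD scheme and the hydrodynamic residuals; 20 random (μ, ξ) draws for the
homography law; and a 9 × 5 (σ/λ, dt) grid for the scale-mapping round
trip (1e−12 relative). These sizes keep the full suite under ten seconds
while leaving each check comfortably inside its asymptotic regime.

## Known limitations

- The reduced rate θ is the only release parameter identifiable from a
  curve; splitting it into (σ, δ) or reporting a fractalization degree
  requires externally chosen (δ; λ, dt) and is flagged as
  convention-dependent. The package deliberately does not guess a
  calibration that would turn stage fits into specific fractalization
  degrees.
- The hydrodynamics module evaluates and verifies the analytic packet
  solution; it does not integrate the hydrodynamic system from arbitrary
  initial data.
- The printed erfc release variant is provided for auditability and
  comparison, not as a recommended fitting function.
- Only 1-D slab geometry with constant σ is treated; no cylinders,
  spheres, or concentration-dependent diffusivity.
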