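# Methods

## The estimation problem

An epithelial sheet is modeled as a planar polygonal tiling: cells are
polygons, cell-cell junctions are straight edges carrying a contractile
tension `T_ij`, and each cell exerts an isotropic 2D pressure `P_i` on its
boundary. If morphogenesis is quasi-static, the forces at every three-way
vertex balance. Writing the balance for all usable vertices gives

    F = C X ≈ 0,

where `X = (T, P)` stacks all junction tensions and cell pressures and `C`
holds purely geometric coefficients: for each junction at a vertex, the
unit vector toward the far endpoint (`a = (cos θ, sin θ)`); for each cell
around the vertex, half the cross-difference of the two flanking loop
vertices (`b = ((y₂−y₁)/2, −(x₂−x₁)/2)`), which is exactly the shoelace
area gradient. With more unknowns than equations, `X` itself is not
recoverable without priors — but substituting a *mechanical model*
`T = T(l, θ; β)`, `P = P(A; β′)` turns the balance into an overdetermined
linear regression in the model coefficients.

### Tension models

Anisotropic spring family (variants A–E):

    T(l, θ) = Λ₀(θ) − Λ₁(θ)·l
    Λ₀(θ) = λ₀(1 + μ₀ cos 2(θ−φ₀)),   Λ₁(θ) = λ₁(1 + μ₁ cos 2(θ−φ₁))

`Λ₀` is an orientation-dependent line tension; `Λ₁ > 0` means shorter
junctions carry *higher* tension — positive feedback between tension/
myosin-II recruitment and junction shrinkage. Variant A is the full model;
B drops `μ₁`; C drops both anisotropies; D drops the spring term; E is
constant tension. All terms are π-periodic in θ (nematic symmetry), which
is why junction angles are folded to `[0, π)`.

Conventional family: `T = Λ₀(θ) + Γ(θ)(L_i + L_j)` with cortical
(perimeter) elasticity `Γ`, in four variants (both anisotropic, each alone,
neither).

Pressure: `P(A) = −kA + P₀` by default, with `k/A + P₀` and
`k·exp(−A) + P₀` as alternatives. `P₀` is structurally unidentifiable: at
an interior vertex the constant-pressure contributions of the surrounding
cells form a closed loop and cancel exactly, so only the `k` column exists
in the design matrix.

### Linearization, scale fixing, and the fit

Each anisotropic coefficient is linear in transformed parameters, e.g.
`Λ₀(θ) = λ₀ + λ₀′ sin 2θ + λ₀″ cos 2θ` with `λ₀′ = λ₀μ₀ sin 2φ₀`,
`λ₀″ = λ₀μ₀ cos 2φ₀`. Only relative forces are observable, so `λ₀ ≡ 1`
fixes the scale and the remaining coefficients minimize `‖F‖²` — ordinary
least squares on `M = C·L`, solved in closed form. Two constraints are
enforced by refitting with SLSQP / bounded least squares only when the
unconstrained optimum violates them: `Γ₀ > 0` (conventional family) and
`λ₁ ≥ 0`, `μ₁ < 1` (the sign of the tension–length correlation must not
invert with angle). Polar parameters are recovered by
`μ = √(λ′²+λ″²)/λ`, `φ = ½ atan2(λ′, λ″)` folded to `[0, π)`; `φ` is
reported as 0 when `μ = 0`.

Model comparison uses `AIC = n log(2πσ̂²) + n + 2(p+1)` with
`σ̂² = FᵀF/n`. `p` counts the free coefficients (the fixed `λ₀` excluded,
`k` included): A→6, B→4, C→2, D→3, E→1; conventional 6/4/4/2. Counting
`λ₀` would shift every AIC by the same +2 and cannot change a selection.

Rank deficiency is detected before solving and raised as a degenerate-
geometry error: on a perfectly regular hexagonal lattice every vertex
equation is identical and the data collapse to a single design point.

### Preprocessing

Junctions shorter than a threshold are excluded (their angle is not
measurable): 3 px is the convention for segmented images, `0.05·√A₀` for
simulated tissues. Cells larger than twice the median area are excluded
(e.g. sensory cells). Coordinates are then divided by `√(median A)` so the
median cell area is 1. Equations are kept only for vertices that are
interior, not flagged as touching the image frame, and whose *every*
incident junction and adjacent cell survived — dropping incomplete rows is
the only choice that keeps each retained equation physically complete.
Excluded junctions and cells also lose their columns.

### Normalized estimates

Estimates are reported dimensionlessly: `λ₀ₙ = λ̂₀/(k̂·A₀^1.5)` and
`λ₁ₙ = λ̂₁/(k̂·A₀)`, with `A₀` expressed in the *fit's* coordinate frame,
i.e. `A₀_true / median(A_raw)`. With that convention the normalized
estimates are exactly invariant to the raw coordinate scale (the scale
factors in `k̂ ∝ s³` and `A₀ₙ ∝ s⁻²` cancel), which the test suite checks
to 1e−9. The only scale-invariant form of `k` itself is
`k̂·A₀ₙ^1.5 = k·A₀^1.5/λ₀` (the reciprocal of `λ₀ₙ`), and that is the
quantity tracked as "k" in the noise report.

Standard errors come from `σ̂²(MᵀM)⁻¹` on the free coefficients, with
first-order (delta-method) propagation — via a numerical Jacobian — to the
derived quantities (`μ`, `φ`, normalized `λ`s); intervals are ±1.96 SE.
They are computed only for unconstrained fits.

### Tension anisotropy summary

`R_T⟨T̂⟩e^{i2Θ} = ⟨T̂e^{i2θ}⟩ − ⟨T̂⟩⟨e^{i2θ}⟩`: the nematic covariance of
predicted tension with junction orientation, normalized by the mean
tension. `R_T = 0` for constant tension or tension uncorrelated with
angle; `T = 1 + cos 2θ` over uniform angles gives `R_T = 0.5`, `Θ = 0`.

## The synthetic-data generator

The cell-vertex model relaxes vertex positions down the gradient of a
virtual work `U₀`: for the anisotropic spring family

    U₀ = Σ_junctions [Λ₀(θ)l − ½Λ₁(θ)l²] + Σ_cells (k/2)(A − A₀)²,

and for the (isotropic) conventional family
`U₀ = Σ Λ₀l + Σ ½ΓL² + Σ (k/2)(A−A₀)²`. Anisotropic Γ(θ) has no
well-defined cell-level potential, so the simulator's conventional family
is isotropic — matching the generating model actually used; anisotropic
conventional variants exist only on the estimation side. Differentiating
`U₀` reproduces the tension and pressure laws, with the simulated pressure
`P = −k(A − A₀)` (linear, basal offset `kA₀`).

Forces freeze the anisotropy factors at the current junction angles
(derivatives of `Λ(θ)` with respect to vertex positions are ignored, the
standard quasi-static treatment), so for isotropic variants the force is
the exact gradient of `U₀` and the energy trace is non-increasing for
sufficiently small Δt; for anisotropic variants the force is the gradient
of `U₀` with `Λ(θ)` held fixed, which the tests verify against central
finite differences.

* Initial condition: a bounded Voronoi tessellation of `n_rows × n_cols`
  uniformly random centroids in a rectangle of area `n_rows·n_cols·A₀`,
  bounded by mirror-reflecting the centroids across the rectangle's sides
  and corners (mean cell area is exactly `A₀` by construction). A single
  seeded generator drives centroid placement; everything downstream is
  deterministic.
* Integration: forward Euler, Δt = 0.1, free boundary (boundary vertices
  move under the same forces; the exterior exerts zero pressure), run to
  t = 5000 — the reference protocol on a 20×20 tile.
* T1 transitions: after each step, interior junctions shorter than
  `0.05·√A₀` whose endpoints are three-way interior vertices may flip: the
  edge is rotated 90° about its midpoint and reconnected; the move is kept
  only if it strictly lowers `U₀`. The trial edge opens to at least the
  threshold length: with the length preserved the energy change of a flip
  is O(l), so at l → 0 a strongly downhill neighbor exchange is invisible
  and the pair stays permanently stuck. The energy test is evaluated on
  the local neighborhood (the five touched edges and four touched cells),
  which is exact because nothing else changes. One ascending-length pass
  per step; vertices of degree > 3 are never split.
* Settling: the main run is followed by a tail of decreasing time steps
  (Δt = 0.05 for t = 200, 0.01 for t = 50, 0.001 for t = 5), repeated
  until one full pass completes without any T1 event, so the run always
  ends on a quiet, fully relaxed stretch (each accepted flip strictly
  lowers `U₀`, so this terminates; capped at 10 passes). The tail serves
  two purposes: junction pairs pinned at the `|l|` kink of `U₀` (flips
  rejected because a four-fold contact is the local optimum) oscillate
  across the kink with amplitude ∝ Δt·|f|, and reducing Δt shrinks that
  oscillation to the quasi-static level the estimator assumes; and the
  long first phase lets the stress redistribution after any late
  neighbor exchange decay before the run ends. It can be disabled per
  config.

Reference study conditions (used throughout the tests and the validation
experiments): anisotropic spring model A with
`(λ₀, μ₀, λ₁, μ₁, k) = (0.2, 0.15, 0.03, 0.5, 1.0)`, `φ₀ = φ₁ = 0`,
`A₀ = 1`, 20×20 cells; conventional isotropic `(Λ₀, Γ, k) = (0.12, 0.04,
1.0)`. Variants B–E use the reference values with the omitted parameters
set to zero.

What the generator does *not* emulate: curved junctions, cell divisions or
extrusions (no T2 moves), junction-level tension fluctuations, external
stress boundary conditions, and systematic segmentation artifacts (merged
cells, missed junctions). Passing the validation experiments therefore
shows the estimator is correct and robust for ideal polygonal quasi-static
tissues with position jitter — not that real segmentation error is as
benign.

## The noise-resistance protocol

Per replicate: a uniformly chosen 10% of vertices get independent Gaussian
offsets on both coordinates (sd = `0.02·√(median A)` for simulated
tissues, `0.05·√(median A)` for segmented ones — the two published
readings of the sd coincide in the normalized frame where the median area
is 1); preprocessing and the fit are re-run from scratch; the relative
deviation `δq = (q_noised − q_reference)/q_reference` is recorded per
parameter (reference = ground truth for simulated data, the original-data
estimate otherwise), plus the Pearson correlation `r` of predicted
junction tensions on the junctions retained by both fits. 100 replicates;
replicate seeds are `seed + index`; medians of `|δq|` and the min/median
of `r` summarize.

Measured behavior at the reference conditions: `r` stays above 0.97 and
the medians for `μ₀` and `k` stay under ~20%, but the spring-constant
quantities `λ₁` and `μ₁` show a *systematic* deviation of ~30–50% that
scales quadratically with the noise sd and is unchanged by deeper
relaxation or stricter junction exclusion. It is an errors-in-variables
effect: jitter violates force balance with errors structured like the
local stiffness matrix, which the regression absorbs by deflating `k` and
the anisotropies and inflating `λ₁` — the weakly identified direction,
since the length-dependent part of tension is only ~10% of the signal at
these parameters. The tension *map* is almost unaffected (hence the high
`r`), but single-parameter readouts of the spring term under vertex noise
should be treated as upper bounds rather than unbiased estimates.

## Numerical choices

* Closed-form `lstsq` for unconstrained fits; `matrix_rank` guard before
  solving; SLSQP (analytic gradient) or bounded least squares only on
  constraint violation, with a boundary flag when the optimum pins a
  constraint.
* `σ̂² = 0` (perfect fit) is reported with `AIC = −∞` and a flag rather
  than an error inside the pipeline; the standalone `aic()` guard raises.
* AIC ties break toward fewer parameters (never observed on continuous
  data).
* Voronoi regions are angularly sorted around their centroid (cells are
  convex at generation time); shared Voronoi vertices keep shared indices,
  so the mesh is watertight without coordinate rounding.
* Degenerate inputs: duplicate centroids are resampled (up to 5 draws);
  zero-length edges contribute zero force direction; cells must have ≥3
  distinct vertices and positive shoelace area after orientation
  normalization.
* JSON round-trips IEEE doubles exactly; the CSV dialect reads with
  `float_precision="round_trip"`.

## Problem sizes in the tests

The unit tests run on 3×3 to 6×6 tiles with shortened relaxations; the
end-to-end validation tests use the full 20×20 / t = 5000 protocol for the
reference recovery, the conventional recovery (3 seeds) and the
100-replicate noise run, and 10×10 / t = 2000 for the 5×5 selection matrix
over 5 seeds — a scale at which the AIC diagonal is already recovered.

## Known limitations

* Only relative mechanical parameters are obtainable (scale fixed by
  `λ₀ = 1`; pressures defined up to a constant).
* No Bayesian per-junction force inference; ground-truth comparison on
  simulations replaces it.
* Tissues whose geometry is too regular (near-hexagonal) leave the
  model parameters near-unidentifiable; the package raises rather than
  extrapolating, but *mild* regularity still inflates the sensitivity of
  `Γ` and `λ₁` to any residual imbalance.
* The vertex-noise `δq` for the spring-constant terms carries the
  systematic bias described above; it is a property of the protocol, not
  of the estimator's consistency on quasi-static data.
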