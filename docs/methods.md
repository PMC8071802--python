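# Methods

This note documents the models implemented in `stalkpath`, the conventions
and numerical choices behind them, and what the synthetic test systems do
and do not establish.

## Order parameter and grid

The collective variable is the number density of hydrophobic (lipid-tail)
particles on a regular collocation grid: a microscopic configuration is
mapped to m̂(c) = (1/ΔV) Σᵢ Π(c, rᵢ) with a separable linear ("tent",
cloud-in-cell) kernel π_α(d) = 1 − |d|/ΔL_α for |d| ≤ ΔL_α.  Conventions:

- **Cell centers at (i + ½)·ΔL_α.**  With minimum-image distances on
  periodic axes this makes the kernel an exact partition of unity, so
  Σ_c m̂(c)·ΔV equals the masked particle count to machine precision —
  a property the test suite checks against a brute-force double loop.
- **Grid derived from the box.**  ΔL = L/n always; an independent ΔL that
  failed to tile the box would break the partition of unity.  Reference
  protocols in the literature quote both rounded per-cell volumes
  (e.g. 0.02 nm³ at 90³ points for a vesicle-scale box, 0.09 nm³ at 20³
  for a small planar box) and nominal cell dimensions whose products differ
  slightly (0.3×0.3×0.2 = 0.018 nm³, 0.3×0.3×0.8 = 0.072 nm³); these
  round-offs are mutually inconsistent, so this package always reports
  ΔV as the product of the derived cell lengths.
- **Hydrophobic selection** is a caller-supplied mask; GRO input defaults to
  the MARTINI POPC tail-bead names (C1A, D2A, C3A, C4A, C1B–C4B),
  overridable for other lipids.

## Umbrella restraint and chemical potential

The restraint is expressed in per-cell bead counts, ΔH = (κ/2) Σ_c
(n(c) − n̂(c))² with κ in kJ/mol (default 50).  The density form
ΔH/k_BT = (λ/2)ΔV Σ(m − m̂)² is recovered with the dimensionless coupling
λ ≡ κΔV/k_BT; the count form is what an MD engine adds to its force
calculation, and it keeps every downstream equation dimensionally
consistent.  Note the symbol collision with the hydration decay length —
here the umbrella strength is always `kappa` and the decay length
`lambda_hyd`.

Forces use the analytic kernel derivative (piecewise-constant slope
±1/ΔL_α); exactly at kernel kinks the left-limit convention applies — a
measure-zero set.  Finite-difference agreement at off-kink positions is a
test invariant.

The chemical potential of a target field is estimated from the mean
restrained deviation, μ(c) = (κΔV/k_BT)[m(c) − ⟨m̂(c)⟩], in k_BT·nm³.  The
estimator is biased at order 1/κ; on a single-cell Gaussian reference model
(closed-form restrained mean) the bias decays with log-log slope −1 across
κ ∈ {25, 50, 100, 200}, which the suite verifies.  All free energies are
reported in k_BT at T = 300 K (k_BT = 2.494 kJ/mol).

Averaging horizons are expressed in sampler steps; an MD-coupled deployment
would map its own sampling window (of order 10 ns per update in published
protocols) onto the same `n_samples`/`n_discard` contract.

## String method

A path of n replicas (24 for vesicle-scale, 19 for small planar systems by
default) is relaxed by alternating:

1. an Allen-Cahn step m ← m − ε·μ per replica, with the default step taken
   from the protocol constant ε·λ/ΔV = 0.03 (ε = 0.03·k_BT/κ);
2. redistribution to uniform arc length: each cell's value sequence is fit
   with a natural cubic spline against the cumulative normalized segment
   lengths Δᵢ (Δᵢ² ∝ Σ_c [m_{i+1} − m_i]², Σᵢ Δᵢ = 1) and re-evaluated at
   uniform positions, iterated up to 5 passes until the Δᵢ are uniform to
   10⁻³ relative.  Endpoints are returned bit-identical.

Design choices where the method leaves freedom:

- **Endpoints evolve by default.**  True minima are fixed points of the
  relaxation, and evolving endpoints cleans imperfect endpoint estimates; a
  `pinned` mode reproduces fixed-state comparisons.
- **Tangents** come from the same natural-spline representation used for
  redistribution (one consistent path model), not finite differences.
- **Natural spline boundary conditions** (zero second derivative at the
  endpoints) throughout.
- **Convergence criteria** are necessarily ours — published protocols report
  only iteration counts (≈200–400 cycles): iteration stops when the maximum
  per-cell displacement per cycle falls below `tol_disp`·max|m| (default
  10⁻⁴) *and* the barrier changes by less than `tol_F` relative (default
  10⁻³).  Non-convergence is a warning with diagnostics, not an exception.
  Diagnostics report string iterations and provider calls separately, since
  a sampled provider dominates the cost in MD-coupled use.
- **Negative densities** arising from an update are clipped to zero (the
  order parameter is a physical density) and counted in the log; clipping is
  switched off for analytic landscapes where negative values are meaningful.

The model-style surface is `StringMFEP(provider, ...).fit()`, which returns
a results object with the converged path, per-replica μ fields, the ΔF(s)
profile, diagnostics, and `summary()`.

## Thermodynamic integration

The free-energy profile is the line integral of the chemical potential along
the path: ΔF(s) = ∫₀ˢ ds′ ΔV Σ_c μ_s′(c)·(dm_s′(c)/ds′), with m and μ
interpolated per cell by natural cubic splines in s and composite Simpson
quadrature on ≥ 201 uniform points (401 by default; cells are processed in
chunks so vesicle-scale grids never materialize a dense × cells array).
An alternative convention that integrates ΔV Σ_c m·μ without the path
derivative appears in print; it is not the differential of F along the path
(it does not vanish for a constant path and is inconsistent with
ΔF(0) = 0), so the gradient line integral is the default and the other form
is available as `form="as_printed"` for comparison.  For exact-gradient
providers the line integral is path-independent and ΔF(1) reproduces the
closed-form endpoint difference to 10⁻⁶ relative — an acceptance invariant.

The barrier ΔF_b = max_s ΔF(s) is refined parabolically around the discrete
maximum, ties breaking toward smaller s.  When μ fields carry sampling
standard errors, per-replica errors are treated as independent and
propagated through trapezoid-level quadrature weights.

## Geometry

All interface measurements use an iso-density threshold on the hydrophobic
density, default 2.2 nm⁻³ (≈ the density at the phosphate/glycerol-defined
membrane interface of a MARTINI POPC bilayer; the bulk tail density is
≈ 5 nm⁻³).  Raising the threshold makes d_w slightly larger and d_st
slightly smaller — a monotonicity the tests enforce on constructed fields.

- **d_w** — per lateral column, below-threshold gaps between above-threshold
  runs are measured with linear sub-cell interpolation, periodically along
  the axis, so a vesicle facing its periodic image is handled transparently.
  Gaps through the interior of a *single* body (e.g. a vesicle's water
  pocket) are excluded by connected-component labels computed with periodic
  lateral connectivity but an open measurement axis — this distinguishes a
  membrane from its periodic image (distinct bodies) while keeping the two
  z-sides of one shell identified.  d_w is the minimal remaining gap, and 0
  when a stalk bridges the membranes.
- **d_st** — at the mid-plane through the center of the minimal gap, the
  above-threshold cross-section containing the density maximum is contoured
  by marching squares; the default diameter is that of the circle with the
  same enclosed area (exact for circular stalks, robust to shape
  fluctuation; a maximal-chord variant is available).  A candidate
  cross-section with another contour nested inside it is rejected: a stalk
  section is a filled disc, whereas a slice through a shell is an annulus.
  This disc-vs-annulus test is the package's resolution of the genuinely
  local ambiguity between a stalk neck and, say, a vesicle equator.
  The mid-plane is located at the minimal-gap center rather than a midpoint
  of body centers of mass, which is ill-defined for a body and its periodic
  image.
- **Azimuthal (R, z) maps** bin cells by lateral minimum-image distance from
  the stalk axis; **thickness profiles** measure per-column above-threshold
  extents of each membrane body against lateral distance from the axis.

## Apposition model

Hydration repulsion between apposed membranes is modeled as exponential,
Δf_flat(d_w) = A·e^(−d_w/λ_hyd) per unit area, calibrated from a single
anchor — for POPC, 1.2 k_BT/nm² at d_w = 1.2 nm with λ_hyd = 0.28 nm
(A ≈ 87.2 k_BT/nm²); a log-linear least-squares calibration over several
points is available.  The Derjaguin approximation gives the finite
vesicle-pair dehydration free energy ΔF = π·R_v·λ_hyd·Δf_flat(d_w), with
R_v the *outer* interface radius.  The planar analogue is proportional to
the contact area and therefore has no area-independent value — only the
patch energy A·Δf_flat is reported, for a stated area.

## Synthetic systems: what they establish and what they do not

The validation landscape is deliberately *not* a lipid force field:

- **Analytic functionals** (quadratic and quartic double-well, optional
  square-gradient penalty with a periodic discrete Laplacian) have exactly
  computable chemical potentials, free energies, minima, and constrained
  barriers.  The curved two-variable double well
  F(x, y) = (x² − 1)² + 2(y − x²/2)² was chosen because its MFEP is bent
  (y ≈ x²/2), so spline reparameterization and tangent projection are
  genuinely exercised; a straight-channel landscape would not test them.
- **The mock sampler** returns the algebraically exact restrained mean
  ⟨m̂⟩ = m − μ/λ, closing the estimator loop with zero statistical noise.
- **Constructed fields** use tanh interface profiles because their
  threshold crossings are closed-form; every fixture stores its ground-truth
  geometry in metadata, so tests never read numbers off a plot.  The default
  construction parameters mirror MARTINI-like membranes: bulk tail density
  5 nm⁻³, membrane thickness 3 nm, interface width 0.15 nm, vesicle outer
  radius 9.2 nm in a 26.3×26.8×20.7 nm³ box (image gap ≈ 2.3 nm), planar
  gap 1.2 nm.
- **The toy Langevin sampler** is an overdamped integrator (stability bound
  dt < γ/k for the stiffest trap) whose restrained averages are compared
  against i.i.d. Boltzmann sampling of the same closed-form equilibrium.

Passing these tests establishes the correctness of the mapping, restraint,
estimator, string, integration, and geometry machinery.  It does **not**
reproduce MD-scale observables — the published stalk-formation barriers
(≈ 24 k_BT) and stalk excess free energies require converged coarse-grained
sampling of ~10⁵-particle systems over hundreds of sampling windows and are
out of scope by design.  Published stalk-diameter values along fusion paths
(0.84–3.6 nm) serve as context for the geometry defaults, not as targets,
because the published diameter's operational definition (area-equivalent,
chord, or contour width) is not stated.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems: 20³–90³
grids for mapping and geometry, 25 replicas on the two-cell landscape, 19
replicas on a 20-cell functional, 10³–10⁴ Langevin samples.  All randomness
flows through explicitly seeded generators; identical seeds and providers
give bit-identical paths, diagnostics, and outputs, and checkpoint-resumed
runs reproduce uninterrupted runs exactly.
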