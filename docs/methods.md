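# Methods

## Physical model

The cytosol is modelled as a Newtonian fluid with the bulk properties of
water at 37 °C; the cytoplasm is ~70 % water, its viscosity is close to
that of pure water, and no cytosol-specific measurements of β, λ or Cp
exist, so water values are the defensible default (all overridable via
`FluidProperties` or YAML).  Density couples to temperature only through
the linear equation of state ρ = ρ0(1 − β(T − T0)); viscosity is constant.
The domain is closed: no-slip membrane (`w1`) and nucleus wall (`w2`),
with fixed wall temperatures, optionally restricted to named heat patches
(mitochondrial clustering) with the rest of the nucleus wall neutral.
Transport through walls, cytoskeletal structure, motor-driven transport
and membrane deformation are all out of scope.

Relevant groups at default scales (L = 10–20 μm, u* ≤ 0.4 μm/s):
Re = u*L/ν ≲ 10⁻⁵, Ga = gL³/ν² ≤ 0.16, Ra = u*L/κ ≲ 5·10⁻⁵, so the
momentum balance is viscous–buoyant (Stokes) and the energy equation is
conduction-dominated.  One consequence used throughout: velocity extrema
are linear in ΔT to well under 1 %.

A note on the velocity reference scale: the dimensionless form sometimes
quoted for this problem uses U = ρ0gL³/μ, which has units m²/s, not
velocity; the package therefore never non-dimensionalizes with it.  The
Rayleigh number is exposed in the velocity-based form Ra = u*L/κ (the
thermal Péclet number), with u* an observed speed, because the flow here
is driven by imposed wall temperatures rather than characterized by a
buoyancy-velocity closure.

## Discretization and solver

Equal-order P1/P1/P1 simplicial finite elements with:

* **PSPG** pressure stabilization, τ_p = h²/(12 μ) per element, including
  the consistent force and advection terms (the viscous residual vanishes
  element-wise for P1);
* **SUPG** streamline stabilization on momentum and on both scalar
  transport equations, τ = [(2|u|/h)² + 9(4α/h²)²]^(−1/2) with α the
  relevant diffusivity — irrelevant for momentum at Re ≪ 1 but essential
  for concentration at cell Péclet numbers up to ~10³;
* an optional **grad-div** term (μ/3)(∇·v, ∇·u) matching the full viscous
  stress of a density-varying flow;
* **hydrostatic splitting**: the static ρ0 g z pressure is removed
  analytically, leaving the buoyancy perturbation ρ0β(T−T0)g ẑ as the
  only body force.  At μm scales the buoyancy force is ~10⁻⁵ of the
  hydrostatic gradient, so solving for the total pressure would lose the
  signal to cancellation;
* **pressure gauge**: one pressure node pinned during the solve, zero-mean
  field reported (an enclosed flow fixes pressure only up to a constant);
* **Picard iteration** between the energy equation and the monolithic
  momentum/continuity block (sparse direct solves).  Convergence is
  declared when the normalized residuals ‖b − Ax‖/(‖|A||x|‖ + ‖b‖) of all
  three equations drop below `tolerance` (default 10⁻⁶); the quiescent
  ΔT = 0 state yields exactly zero residuals.  Because the advective
  couplings are O(Re) and O(Ra), one or two iterations suffice; the
  budget is 200 with divergence declared if the residual grows 10× above
  its running minimum.  A segregated pressure-correction loop would be an
  equally valid path to the same converged residuals.

Default "full" mode keeps the variable-density terms in inertia and
continuity (∇·(ρu) = 0 with the element-wise ∇ρ from the equation of
state); the Boussinesq switch drops them.  At β·ΔT ≤ 0.005 the two agree
on velocity maxima to ~0.1 % (tested at 1 %).

The concentration equation ∇·(uC) = D∇²C uses the same scalar machinery
plus a lagged residual-based discontinuity-capturing viscosity
(ν_sc = ½h|u·∇C|/|∇C|, capped at the first-order-upwind level, ≤ 8 fixed-
point iterations); this keeps C within its boundary bounds to 10⁻³ even at
D = 10⁻⁵ μm²/s.  The wall opposite the C = 1 source is an absorbing C = 0
Dirichlet boundary — a modelling choice: with a zero-flux wall the steady
problem would be trivially uniform.

## Meshing

No external mesh generator is assumed.  Two families cover all domains:

* **2-D star domains**: both walls are star-shaped about the nucleus
  center (true for discs, rectangles and convex polygons with an interior
  nucleus), so a structured grid of rays × radial layers gives a
  boundary-conforming triangulation with exact `w1`/`w2`/patch tagging.
* **3-D spherical shells**: a subdivided icosahedron is extruded radially
  from the (possibly eccentric) nucleus sphere to the membrane sphere;
  each prism is split into three tetrahedra with diagonals chosen through
  the globally smallest vertex index, which guarantees conformity between
  neighbours.

Defaults: 2-D target edge 0.6 μm (~10³ nodes); 3-D icosphere subdivision 3
with 8 radial layers (5 778 nodes, 30 720 tetrahedra).  These are the
problem sizes used by the test suite and the acceptance script.  Meshed
fluid volume is within 1 % of the analytic value at defaults (0.13 % in
2-D, 0.9 % in 3-D) and converges under refinement; `Mesh.validate()`
checks element orientation, the tag partition of the topological boundary,
and region connectivity.  Boundary polygons/polyhedra are inscribed in the
analytic walls, so meshed domains are slightly smaller than their analytic
counterparts — relevant when comparing to closed-form solutions.

## Verification against independent oracles

Two closed-form routes, independent of the FEM code path, anchor the
solver (both are frozen into the test suite):

* **Conduction limit** (g = 0 or u = 0, concentric walls): the analytic
  1/r (3-D) and log-r (2-D) profiles.  L2 agreement: 0.01 % in 2-D,
  0.3 % in coarse 3-D — also used for the concentration equation, where
  swapped source walls must give complementary fields (machine precision).
* **Buoyant Stokes flow, concentric annulus**: the mode-1 stream-function
  reduction (∇⁴ψ in 2-D, E⁴ψ in 3-D) with the conduction temperature as
  forcing, solved as a two-point BVP with `scipy.integrate.solve_bvp`.
  At ΔT = 1 °C the 2-D FEM maxima match the oracle to 0.3 %
  (0.001337 vs 0.001335 μm/s upwelling); the 3-D axis peak is ~8 % low at
  default resolution and converges under refinement.

With the default eccentric geometry (nucleus 2 μm off-center — the offset
is a modelling default, not a measured value) the computed maxima are
0.0020 μm/s upwelling / 0.0015 μm/s downwelling at ΔT = 1 °C in 3-D,
scaling linearly to 0.026 μm/s at ΔT = 13 °C.  A hand scaling check agrees:
conduction-regime slot convection gives u ~ gβΔTd²/ν × O(10⁻²) ≈ 10⁻³ μm/s
for the ~5.7 μm mean gap.  Literature-reported magnitudes for nominally
comparable configurations are of order 0.03 μm/s per °C — about 14× larger
than both our FEM solution and the independent closed-form oracle — and we
have not been able to reconcile that factor with the stated governing
equations and parameters (the dimensionally inconsistent U above is a
plausible origin).  The package reports the computed values; the strict
literature-comparison test in `tests/test_acceptance.py` is left failing
rather than rescaled.

## Particle tracking

Inertialess (overdamped) Euler–Maruyama updates
x ← x + u(x)Δt + √(2DΔt)ξ: at d_p = 0.1 μm the particle Reynolds and
Stokes numbers are vanishingly small.  Velocity is interpolated element-
locally (barycentric weights; candidate elements from a k-d tree over
centroids, with graceful clipping at the inscribed-boundary sliver).
Wall collisions reflect specularly off the analytic wall surfaces, which
conserves particles in the closed domain.  The Stokes settling velocity
(ρ_p − ρ_f)gd_p²/(18μ) ≈ 4.5·10⁻⁴ μm/s for the default 1050 kg/m³, 0.1 μm
particle — under 2 % of the ΔT = 1 °C flow speed — is implemented but off
by default.  Determinism: one `numpy.random.default_rng(seed)` stream per
particle, so ensemble members are bit-identical to single runs.

The transport-regime classifier compares the ensemble-mean drift distance
accumulated along the local flow direction, Σ Δx·û(x), against the
Brownian scale √(2dDt); ratios above 2 are convection-dominated, below ½
diffusion-dominated, else mixed.  The observation window (default
dt = 0.01 s × 1000 steps = 10 s), start point (−2, −2) μm and threshold
factor are explicit parameters: the regime boundary in (ΔT, D) scales
with √t, so any statement about where convection "wins" must fix the
window.  With the computed velocity scale and a 10 s window, D = 0.1 μm²/s
at ΔT = 1 °C is solidly diffusion-dominated, and convection dominance at
D = 10⁻³ μm²/s requires gradients beyond the swept 13 °C or windows of
minutes — consistent with the qualitative conclusion that trajectory-level
dominance needs stricter conditions than Pe > 1 alone.

## Synthetic domains

The generator produces the study geometries without any image input:

* **Epithelial sheets**: 8 columnar cells (10 × 25 μm defaults; the cell
  dimensions are package defaults, config-exposed) in eight variants, each
  differing from baseline A in exactly one feature — nuclear temperature
  (B), nucleus elevation patterns (C–E; E seeded), elliptical nuclei of
  equal area (F), apical location (G), one-sided heating (H).
* **Multicell clusters**: Lloyd-relaxed Voronoi tessellations (~45 μm mean
  cell diameter, seeded), shrunk so cells are hydraulically independent,
  each with an interior circular nucleus at 8 % of cell area and a heat
  patch covering a set fraction of the nucleus wall on a random side.
  Gravity is fixed in-plane (−x₂) and recorded in the scenario.

What this emulates: per-cell closed circulations, heterogeneous heating
geometry, pseudo-stratification.  What it does not: real image-derived
outlines, nucleus shape irregularity, inter-cell coupling through gap
junctions, cytoskeletal obstruction.  Passing tests on these domains show
the pipeline is correct on its stated model, not that real epithelial
flow fields look like this.

## Numerical choices and degenerate inputs

* Geometry in μm, SI inside the solvers, °C only at the presentation
  layer; each conversion happens exactly once.
* ΔT = 0 short-circuits nothing: the same code path returns u = 0 with
  exactly zero residuals.
* g = 0 is allowed (conduction oracle); all other fluid properties must
  be strictly positive.
* Plane-flux integration nudges the plane a quarter element off any mesh
  line of nodes (structured meshes place node lines exactly at mid-height).
* Non-convergence raises a `ConvergenceError` carrying the residual
  history; sweeps record failed rows instead of dropping them.
* Mesh tag lookups match either an exact tag name or its per-cell
  suffixed variants (`w2` matches `w2:3`), so thermal settings apply
  uniformly or per cell.

## Known limitations

* Steady solutions only; transient onset and oscillatory regimes are out
  of scope (at these Rayleigh numbers the steady branch is the relevant
  one).
* P1 velocity/pressure is first-order in pressure; peak-velocity accuracy
  at default 3-D resolution is ~5–10 % (the acceptance comparisons allow
  for this; refine `subdivisions`/`n_radial` for better).
* The 3-D mesher requires a spherical nucleus; ellipsoidal nuclei are
  2-D-only.
* Specular reflection is the only wall interaction for particles; no
  hydrodynamic wall drag or adsorption.
* Polygon membranes must be star-shaped from the nucleus center (convex
  suffices); strongly non-convex real cell outlines would need a
  different mesher.
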