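# Methods

## Model

A huddle of N emperor penguins is a set of occupied sites on a hexagonal
lattice with unit spacing (one penguin diameter), connected, hole-free, with
every penguin touching at least two others.  The boundary polygon connects
the centres of the penguins with fewer than six neighbours, traversed
counterclockwise; the wind blows along +x.

Each iteration relocates exactly one penguin:

1. **Wind.**  The flow outside the huddle is steady, inviscid and
   irrotational.  Its complex potential is `F(S⁻¹(z))`, where
   `F(ζ) = ζ + 1/ζ` is the Joukowsky potential of uniform flow past the
   unit disk and `S` is the exterior Schwarz–Christoffel map from the
   outside of the disk to the outside of the (rescaled) huddle polygon.
2. **Temperature.**  In nondimensional variables (lengths over the
   equal-area-disk radius `L = √(N·A_cell/π)`, `A_cell = √3/2`; temperature
   between the ambient 0 and the huddle-edge 1; velocity over the far-field
   wind speed), the temperature solves `Pe (u·∇T) = ∇²T`.  This equation is
   conformally invariant for potential-flow velocities, so it is solved
   once on the canonical annulus `1 ≤ r ≤ R` with the disk flow and
   Dirichlet values T(1)=1, T(R)=0; only the boundary correspondence
   changes as the huddle evolves.
3. **Heat loss.**  The outward flux density at the unit circle is the
   one-sided difference `f(θ) = (T(1,θ) − T(1+Δr,θ))/Δr`.  Penguin *i* on
   the boundary loses `q_i = ∫ f dθ` over its preimage arc, delimited by
   the preimages of the physical midpoints between consecutive boundary
   penguins.  Interior penguins lose a negligible amount (q = 0).
4. **Noise (optional).**  `q_eff,i = q_i + ε·Q̄·η_i` with `η_i`
   uniform on (−0.5, 0.5), redrawn every iteration.  `Q̄` is the mean
   boundary loss of the deterministic disk-shaped huddle of the same N,
   computed once per run.
5. **Relocation.**  The boundary penguin with the highest effective loss
   whose removal keeps the huddle valid vacates its site and re-attaches at
   the free site adjacent to the two chosen neighbours: the least-loss
   boundary penguin and, among its boundary neighbours, again the
   least-loss one.

## Numerical choices

**Exterior SC map.**  For corners `w_k` with turning angles `π·β_k`
(Σβ_k = 2) the derivative is `f'(ζ) = C·Π(1 − z_k/ζ)^{β_k}` with
prevertices `z_k = e^{iθ_k}` and single-valuedness condition
`Σ β_k z_k = 0`.  Collinear boundary penguins carry zero turning and are
dropped as map vertices (they are reinstated through side-arclength
interpolation when preimages are needed).  The parameter problem is solved
in log-gap variables with θ₁ gauge-fixed, matching n−3 side-length ratios
plus the two closure components, by a quasi-Newton root finder.  Cold
starts are seeded by a multiplicative fixed-point sweep that nudges each
prevertex gap toward its side-length share — cheap, globally stable, and
sufficient for the very irregular many-cornered polygons that random
initial huddles produce; within a run, each solve warm-starts from the
previous iteration's prevertices matched corner-to-corner.  All circle-arc
integrals use compound Gauss–Jacobi quadrature (singular endpoint panels
plus geometrically graded Legendre panels; quadrature order escalates
(8,1)→(12,2)→(16,3) until the vertex-image residual stabilises).
Tolerances: vertex-image residual `tol_map = 1e-6`, inverse-map round trip
`tol_inv = 1e-8`, both far below the thermal grid error; a residual above
1e-3 raises a map failure.  Prevertex gaps below 1e-6 rad raise a crowding
warning but not an error: exterior maps crowd far more mildly than
interior ones, and the aspect ratios reached here stay well within double
precision.  After each solve the canonical frame is rotated so that C is
real positive, aligning the canonical far-field flow with the physical
wind; |C| is then the logarithmic capacity of the polygon exterior (unit
tests pin it against the closed form for a square).

**Annulus solve.**  Uniform polar grid, centred differences, sparse direct
solve; defaults `R = 4`, `n_r = 60`, `n_θ = 180`.  Centred differencing is
retained at all Pe (upwinding would change the discrete operator); a cell
Péclet number above one triggers a stability warning with suggested sizes,
and `suggested_grid(Pe, R)` returns resolutions satisfying
`Pe·|u_r|·Δr/2 ≤ 1` and `Pe·r·|u_θ|·Δθ/2 ≤ 1` (the angular constraint is
dominated by `r·|u_θ| ≈ R + 1/R` at the rim).  Sweeps over Pe use these
suggested grids.  The canonical field depends only on (Pe, R, grid), so it
is solved once and cached per parameter set.

**Flux accounting.**  The printed inward one-sided difference is negated so
that q > 0 ("heat is always lost"); its O(Δr) bias is accepted because only
the relative profile drives the dynamics.  Per-penguin integrals use the
exact cumulative of the periodic linear interpolant of the flux samples,
so Σq_i equals the full-circle integral to machine precision.

**Degenerate states.**  A mover whose removal would disconnect the huddle,
strand a neighbour below two contacts, or pinch the boundary polygon is
skipped in decreasing-loss order.  If the designated destination cell is
occupied or ineligible, the next-best second neighbour is tried, then the
next-best first neighbour (a deterministic cascade; the rule's intent is
kept, only totalised).  The vacated site is used only when nothing else is
eligible; in the deterministic limit that would freeze the huddle and is
reported as a stuck state.  Exact loss ties break on the lower traversal
index.

**Randomness.**  One master seed spawns two independent streams (initial
huddle growth; noise draws), so initial conditions are reproducible across
ε sweeps.  Initial huddles grow from a fixed compact five-penguin seed by
uniform draws over the eligible sites (rejection sampling over a cheap
superset keeps growth of hundreds of penguins fast while preserving
uniformity).  The five-penguin arrangement is a fixed choice; steady-state
results are insensitive to it.

**Q̄ convention.**  The disk-reference loss averages over the *boundary*
penguins of the disk huddle.  Averaging over all N would shrink the noise
scale as the huddle grows (interior penguins contribute zero), decoupling
ε from the per-move decision it is meant to perturb; the all-N mode is
available as an option.

**Capacity correction.**  The canonical Péclet number is used as given,
with `F = ζ + 1/ζ` — the construction the model implies.  Because the
physical far-field speed transforms by 1/|C| and |C| ≈ 1 for the near-disk
polygons arising here, the distinction is a percent-level effect; an
option flag multiplies Pe by the capacity for sensitivity checks.

## Diagnostics

Width and length are axis-aligned extents, centre-to-centre plus one
lattice unit.  Protuberance exclusion (used for aspect ratios of noisy
huddles) keeps penguins with ≥ 3 neighbours, the simplest filter that
removes one-penguin-wide chains.  The steady-state iteration is the first
after which the width is constant for a 2N-iteration window.  Waiting
times are per-penguin gaps between successive relocations divided by N,
pooled across penguins with censored first/last intervals dropped; the
random-mover reference has normalized mean 1 and sd √(1 − 1/N) (geometric
law).  Downwind drift is the slope of the centroid x-coordinate over the
steady window.

## Problem sizes used in the test and acceptance runs

Deterministic shape results use N = 100 with 320–500 iterations (steady
state is reached near iteration 100); the Péclet sweep runs Pe ∈ {1, 10,
100} at N = 100, where the same log–log slope band applies as for larger
huddles; equal-access statistics use N = 40 with 1600 iterations so that
nearly every penguin relocates many times; the outer-radius study compares
R ∈ {2, 3, 4, 8}.  These sizes keep full runs in the minutes range while
preserving every qualitative regime of the model.

## What the synthetic inputs do and do not cover

All inputs are generated programmatically: random initial huddles, the
deterministic disk reference, and crafted fixtures (filled hexagons,
strips, dumbbells) with closed-form geometry.  The model idealises real
huddles: uniform penguin size on a perfect lattice, a single huddle,
steady unidirectional wind, two-dimensional transport, no heat loss
through feet, eyes or the huddle top (all of which affect penguins roughly
equally and so cancel from the relocation decision).  Passing tests
therefore validate the model's internal behaviour — shape selection,
scaling with Pe, fairness of exposure — not quantitative agreement with
field data.

## Independent checks

The conformal stack is validated against closed forms (square capacity,
regular-polygon prevertex symmetry, harmonic annulus solution), adaptive
refined quadrature, and Pick's-theorem polygon areas.  End to end, a
9-penguin huddle at Pe = 5 is re-solved by a direct Cartesian
finite-difference discretisation in the physical plane (no conformal map
in the PDE path); identically probed boundary-flux profiles from the two
routes agree within 5% relative L² error.  The flux probes sit at a finite
distance from the boundary because the flux density diverges like
d^(−1/3) at convex corners — pointwise agreement at the corners themselves
is not attainable by any finite-difference oracle.

## Known limitations

In this implementation the steady-state spread of the per-penguin losses
(q_max − q_min ≈ 2.6·Q̄ at N = 100, Pe = 10) exceeds the ε = 2 noise range
(ε·Q̄), so runs at ε = 2 equilibrate at core aspect ratios near 1.6 rather
than fully circular; noise dominates the relocation decision, and huddles
become essentially round, only for ε ≳ 3.  The acceptance suite measures
and reports this at ε = 2.

Very large ε with large Pe can propose moves whose acceptance would
enclose empty space; such movers/destinations are skipped and counted
rather than accepted.  Extremely elongated huddles (aspect ratios far
beyond those reached at Pe ≤ 100) would eventually crowd prevertices below
the warning threshold.  The one-sided flux bias slightly flattens the
absolute profile; all reported dynamics depend only on loss rankings.
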