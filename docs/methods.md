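# Methods

This note documents the models implemented in `leafsim`, the parameters
that matter, the numerical choices behind them, and what the synthetic data
does and does not capture.

## Contour reconstruction

Leaf boundaries enter as an ordered closed loop of at least four key
points. The loop must be simple (validated with shapely) and free of
coincident consecutive points. A **periodic cubic interpolating spline**
(scipy `CubicSpline`, `bc_type="periodic"`) is fitted over chord-length
parameters normalized to [0, 1); interpolation rather than approximation is
used so the curve passes through every picked point (verified to 1e-9).
Resampling is uniform in arc length via a cumulative chord table over 1024
dense segments inverted by linear interpolation; the first sample is always
the first key point. Defaults: spline degree 3 (fixed), 64 boundary samples
(configurable). Both choices were genuinely open; cubic interpolation is the
lowest degree giving tangent-continuous closed curves, and 64 samples keeps
boundary edges comparable to the interior target edge length.

## Triangulation and optimization

The boundary polygon is triangulated by **incremental insertion**
(Bowyer–Watson over a super-triangle), then constrained to the polygon:
missing boundary segments are recovered by flipping crossing edges, and
triangles whose centroid falls outside the polygon are culled. In-circle
tests use the 3×3 determinant with a relative tolerance of 1e-12 scaled by
the fourth power of the data extent; near-co-circular configurations are
resolved by insertion order, which makes results deterministic.

Boundary-only triangulations of elongated leaves contain slivers, so the
mesh is optimized by repeating two steps per pass:

1. **Relocation** — each interior vertex moves to the area-weighted
   centroid of its incident triangles. The move is *guarded*: it is
   rejected if it would invert a triangle or reduce the minimum incident
   interior angle. The guard is what makes the mesh minimum angle
   non-decreasing across passes, which plain Laplacian smoothing does not
   guarantee.
2. **Reconnection** — Delaunay edge flips until no interior edge violates
   the empty-circumcircle criterion.

When a target edge length is set, centroids of triangles whose longest edge
exceeds 1.5× the target are inserted (triangle split followed by flips)
until the median edge length reaches the target. The default iteration
count is 160 passes; passes stop early once no vertex moves more than
1e-10× the mesh extent and no flips occur, which also makes re-optimizing a
converged mesh a no-op. Boundary vertices are never moved — their
coordinates are bit-identical before and after.

Texture coordinates are the vertex positions normalized into the boundary's
bounding box; they exist so the mask map can be addressed per vertex.

## Mass-spring deformation

Vertices are particles, unique mesh edges are springs with rest length
equal to the initial edge length. Constraints are built by the
flag-traversal procedure (visit particles in index order; connect only to
not-yet-visited neighbors), which yields each undirected edge exactly once.

**Masses.** Each particle's mask pixel is found by nearest-pixel lookup at
its uv coordinate (uv origin at the image's lower-left). The mass is 0.5
for a black pixel and ln(gray + 1) otherwise, giving masses in
[0.5, ln 256] ≈ [0.5, 5.55] that increase with brightness. The explicit
branch at zero avoids ln 1 = 0, i.e. massless particles. The logarithm
compresses the 8-bit range so mass contrasts stay gentle.

**Forces.** The force on a particle is the sum of linear Hooke spring
forces −k(|p| − L)·p̂ over its springs, a velocity-proportional damping
−c·v, and an external field force. The external term is a *force field*
independent of mass (default in the pipeline: a constant downward vector of
magnitude `gravity`). This is deliberate: with equal force per particle,
acceleration a = F/μ differs by mass, which is the entire mechanism by
which the mask steers deformation. A mass-proportional gravity would cancel
it.

**Integration.** Explicit Euler in the exact order: acceleration from the
forces at time t; velocity from the new acceleration; position from the new
velocity. Defaults Δt = 0.005, stiffness 50, damping 0.1 satisfy the
stability requirement Δt·√(k/μ_min) = 0.05 ≪ 1 for mask-derived masses.
Non-finite forces or positions raise an error naming the particle and step.

**Velocity constraint.** After the velocity update and before the position
update, every spring's predicted relative position
P_uv(t) + V_uv(t+Δt)·Δt is checked against the bound (1 + τ_c)·L
(τ_c = 0.1 by default, capping stretch at 110 %). Offenders have their
relative velocity reduced along the predicted axis so the next length lands
exactly on the bound; the correction splits equally between two free
endpoints and falls entirely on the free one when the other is anchored
(two violated anchored endpoints are a configuration error). Sweeps run
over constraints in ascending index order; `n_constraint_passes` (default
3) full sweeps always run, and sweeping continues until no violation
remains (hard cap 2000 extra sweeps, beyond which a numerical-instability
error is raised). Running to quiescence is this package's choice: the
elongation bound is a guarantee, not a best effort, and heavily loaded
meshes can need a few hundred Gauss–Seidel sweeps before every spring's
prediction is inside its bound. The violation test carries a 1e-10 relative
slack that absorbs the floating-point limit cycle of repeated projections —
two orders of magnitude inside the 1e-9 tolerance at which the bound is
asserted.

Only structural springs (mesh edges) exist; there are no shear or bend
springs and no self-collision handling. The upper/bottom structural
difference of a real leaf is represented solely through the mask. Anchoring
is optional: vertices within a configurable radius of a designated petiole
point are held fixed for the whole run.

## Markov senescence

States are indexed 0…n−1 and carry opaque texture labels plus optional
snapshot references; the state count is fully user-defined. For a step of
duration t under environment e, self-retention is
P_ii(e,t) = exp(−ln2/τ_i(e)·t): at t = τ_i(e) the probability is exactly
one half, and the diagonal satisfies the exponential semigroup property
P_ii(t₁+t₂) = P_ii(t₁)·P_ii(t₂). Both τ_i(e) and the transition weights
X_ij(e) are bilinear interpolations over normalized temperature and
humidness of four constants fixed at the extremes, ordered
**(dry-cold, dry-warm, wet-cold, wet-warm)** in every file and array — the
ordering is a convention this package fixes once.

The interpolated X_ij over j ≠ i are renormalized to sum to one before
use; without renormalization the row P_ij = (1 − P_ii)·X_ij would not be
stochastic for arbitrary user corners. A transient state whose weights are
all zero is a specification error (the leaf could never leave). Absorbing
states (e.g. fallen) have diagonal 1.

Populations evolve in **discrete epochs**: one transition-matrix sample per
(environment, duration) pair, rather than continuous-time event
simulation. Randomness derives from one integer seed: epoch k uses the
SeedSequence substream `(seed, spawn_key=(k,))` and draws a uniform vector
indexed by leaf id, so results are independent of leaf processing order and
bit-reproducible. The sampler's only inputs are the current assignments and
the epoch's matrix — the chain is memoryless by construction.

## Synthetic data

The generators emulate the three hand-made inputs of the real workflow:

- **Outlines**: ellipses, or lobed silhouettes
  r(θ) = R(1 − depth·|sin(kθ/2)|^p) with seeded radial jitter of at most
  2 % of R. Defaults (5 lobes, depth 0.5, sharpness 1.5, 32 key points,
  2 % jitter) give a maple-like simple polygon. This is a stand-in for a
  scanned contour: it has lobes and mild irregularity but none of the
  fine serration or asymmetry of a real leaf.
- **Masks**: dark-edge (dark value 16 within a 0.15-unit band of the
  boundary, bright 200 elsewhere) and bright-vein (bright 200 within a
  0.08-half-width vertical midrib corridor, dark 16 elsewhere), both
  computed with exact point-to-segment distances so the band does not
  depend on raster resolution; pixels outside the polygon read 255.
  Real hand-painted masks have soft gradients; these are binary, which
  makes the dark-versus-bright displacement comparisons crisp but ignores
  intermediate stiffness.
- **Senescence specs**: feed-forward chains with one absorbing final
  state, half-life corners drawn uniformly in [5, 60] time units and
  forward weights in [0.6, 0.95] with a small skip probability. The ranges
  are stated here as the package's defaults for a plausible seasonal
  progression where each stage lasts days to weeks on the schedule's time
  scale.

Passing tests on these fixtures demonstrate the algorithms' contracts —
bounds, conservation, convergence, distributional agreement — not fidelity
to any particular botanical species or scan.

## Problem sizes and tolerances

The test and acceptance workloads use a 48-point boundary refined to
roughly 170 vertices / 300 triangles, 500 integration steps, and
populations of 10,000 leaves over 5 epochs — sizes at which every guarantee
is exercised in seconds per case. Key tolerances: spline interpolation
1e-9; triangulation area conservation 1e-9; elongation bound 1e-9;
half-life identity, row sums, and semigroup identity 1e-12; Monte-Carlo
agreement three binomial standard errors. Co-circular Delaunay ties are
compared up to tie permutations using the same determinant measure at 1e-10
relative tolerance.

## Known limitations

- The constrained triangulation's edge recovery assumes a simple polygon;
  nearly-degenerate inputs (collinear runs, microscopic edges) can exhaust
  the flip search and are rejected with an error rather than repaired.
- Explicit Euler with velocity clamping is robust at the default step but
  is first-order; energy behavior is only qualitatively physical.
- The Gauss–Seidel constraint sweep is O(violations) per sweep in Python;
  very large meshes (tens of thousands of springs) would want a vectorized
  or compiled projection loop.
- Texture handling is purely nominal: states carry labels, and no images
  are rendered or mapped.
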