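# leafsim

Simulation of the life cycle of a leaf: how a scanned outline becomes a
triangular mesh, how that mesh withers and curls as the leaf dehydrates, and
how a whole population of leaves drifts through senescence states — green,
yellow, brown, fallen — as the seasons change.

`leafsim` is aimed at researchers in computational plant morphology and
procedural modeling who need a reproducible, scriptable implementation of
three coupled pieces:

1. **Geometry.** A closed periodic cubic B-spline is interpolated through
   key points on the leaf edge, resampled uniformly in arc length, and
   triangulated by incremental insertion (Bowyer–Watson) constrained to the
   leaf polygon. A two-step optimization loop — relocate interior vertices
   to the area-weighted centroid of their star, then restore the Delaunay
   property by edge flips, optionally inserting interior points down to a
   target edge length — turns the initial long, narrow triangles into an
   even-sized mesh.
2. **Deformation.** The mesh becomes a mass-spring system: vertices are
   particles, edges are springs at their initial rest length *L*. Particle
   masses come from a grayscale *mask map* through per-vertex texture
   coordinates,

   ```
   m = 0.5        if gray = 0
   m = ln(gray+1) otherwise
   ```

   so dark-painted regions are light and curl first under a field force.
   Integration is explicit Euler (a = F/μ, v ← v + Δt·a, P ← P + Δt·v), and
   over-elasticity is clamped by a velocity constraint: for every spring the
   predicted relative position must satisfy |P(t) + V(t+Δt)·Δt| ≤ (1+τ_c)·L,
   so with τ_c = 0.1 no spring ever stretches past 110 % of rest length.
3. **Seasons.** Leaf appearance states form a Markov chain conditioned on a
   normalized environment e = (temperature, humidness) ∈ [0,1]².
   Self-retention over time t is P_ii(e,t) = exp(−λ_i(e)·t) with
   λ_i(e) = ln2 / τ_i(e), where the half-life τ_i(e) is bilinearly
   interpolated from four constants given at the environmental extremes
   (dry-cold, dry-warm, wet-cold, wet-warm). The leaving mass 1 − P_ii is
   split among successors by interpolated weights X_ij(e), renormalized per
   row. Populations of leaves are evolved leaf-by-leaf with seeded,
   order-independent sampling.

No external data is needed: `leafsim.synthetic` generates lobed "maple"
outlines, edge-dark or vein-bright mask maps, and feed-forward senescence
specs, all deterministic in their seeds.

## Worked example

```python
import numpy as np
import leafsim as ls

# 1. geometry: synthetic maple outline -> spline -> optimized mesh
outline = ls.make_outline(ls.OutlineRecipe(shape="maple", n_keypoints=32,
                                           seed=7, jitter=0.02))
boundary = ls.sample_curve(ls.fit_closed_bspline(outline), 48)
mesh = ls.optimize(ls.triangulate(boundary), iterations=60, target_edge=0.12)
print(len(mesh.vertices), ls.quality(mesh))

# 2. deformation under a dark-edge mask and constant downward force
mask = ls.make_mask(ls.MaskRecipe(pattern="dark-edge"), boundary)
config = ls.SimConfig(external_force=ls.constant_force([0, 0, -2.0]))
snaps = ls.simulate(mesh, mask, config, n_steps=500, snapshot_every=1)
cons = ls.build_constraints(mesh)
elong = max(np.max(cons.current_lengths(s.vertices3) / cons.rest_lengths) - 1
            for s in snaps)
gray = mask.values_at_uv(mesh.uv)
disp = np.linalg.norm(snaps[-1].vertices3 - snaps[0].vertices3, axis=1)
print(f"max elongation {elong:.6f}")
print(f"dark regions moved {disp[gray < 64].mean():.3f}, "
      f"bright {disp[gray > 192].mean():.3f}")

# 3. seasons: 10,000 leaves through five epochs of a fixed environment
spec = ls.make_default_spec(3, seed=1)
env = ls.Environment(temperature=0.7, humidness=0.3)
pop = ls.evolve_population(ls.LeafPopulation.uniform(10_000, rng_seed=5),
                           [(env, 5.0)] * 5, spec)
print(pop.history[-1] / 10_000)
```

prints

```
174 MeshQuality(min_angle=33.01719390214035, edge_length_cv=0.17735041927562828, triangle_count=298)
max elongation 0.100000
dark regions moved 1.662, bright 1.459
[0.6976 0.219  0.0834]
```

The optimized mesh has even triangles (minimum angle 33°, edge-length CV
0.18). The maximum spring elongation over 500 steps is exactly the τ_c = 0.1
cap — 10 % — never beyond it; dark-masked vertices (light particles) moved
about 14 % further than bright ones, which is the mask-steered differential
curling. The final population fractions (70 % green, 22 % yellow, 8 %
fallen) agree with the analytic matrix-power distribution to Monte-Carlo
accuracy.

A batch CLI wraps the same pipeline:

```bash
leafsim run --config config.json   # writes mesh.obj, snapshots, mask.png,
                                   # population_history.csv, manifest.json
```

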