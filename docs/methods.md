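# Methods

## Contact graphs

A configuration is a set of coarse-grained sites in an orthorhombic
periodic box (coordinates in nm). Surfactant molecules are linear 3-bead
chains — polar head, middle tail bead, terminal tail bead — with 0.47 nm
bead spacing, the canonical coarse-grained geometry of an
octyltrimethylammonium-like cation. The contact graph has one node per
molecule owning tail-role sites; molecules `i ≠ j` are joined iff the
minimum over their tail-site pairs of the periodic minimum-image distance
is *strictly* below the cutoff (ties at exactly the cutoff are excluded).
The default cutoff is 0.7 nm, the first minimum of the tail-site RDF in
this family of surfactant systems; it must stay below half the smallest
box edge for the minimum-image convention to hold. Neighbour search uses a
periodic k-d tree (`scipy.spatial.cKDTree` with `boxsize`), then candidate
pairs are re-measured with explicit minimum-image arithmetic; a property
test checks the result against an all-pairs 27-image brute force.

## Centralities

Degree, closeness, betweenness and clustering are delegated to networkx
and validated against independent brute-force oracles (Floyd–Warshall
distances, distance-matrix path counting, triple-loop triangle counts) on
hundreds of random graphs.

Two definitional choices deserve note:

- **Closeness** uses the Wasserman–Faust composition
  `C_c(v) = [n_v/(N−1)]·[n_v/Σd]` with `n_v` the reachable-set size
  (excluding `v`). This is the only form that behaves sensibly on the
  disconnected graphs of the micellar regime; it reduces to classical
  closeness `(N−1)/Σd` on connected graphs and scores isolated nodes 0.
  One caution: closeness is monotone under edge *addition within a
  component* but **not** under edges that merge components — a new bridge
  can flood a tightly-knit node with distant vertices and lower its score.
  The test suite asserts the intra-component monotonicity only.
- **Clustering** defaults to the literal form `T(v)/(deg(v)(deg(v)−1))`,
  half the common definition; pass `convention="standard"` for
  `2T/(k(k−1))`. Both are exposed because published values computed with
  either convention differ exactly by this factor 2.

Betweenness is reported raw (sum over unordered pairs, endpoints
excluded, ties split by shortest-path counts); normalization by
`(N−1)(N−2)/2` is opt-in.

## Node-based fractal dimension

For origin `i`, the mass function `M_i(r)` counts nodes within `r` hops
(BFS). The NFD is the least-squares slope of `ln M` vs `ln r` over the
**upper scaling window** `[max(2, r_fit//3), r_fit]`, where `r_fit` is the
largest radius with `M(r) < 0.5 ×` component size. Three regions are
deliberately excluded, as is standard in box-counting practice:

- `r = 1` (pure degree, not scaling),
- the small-r transient (on a periodic square lattice the exact ball
  `M = 2r² + 2r + 1` only approaches slope 2 from below; fitting from
  r = 1 underestimates the dimension by ~0.3),
- the saturation plateau (beyond half the component the ball closes on
  itself and the curve bends).

With this window the estimator recovers 0.98 on a 200-ring, 1.87 on a
30×30 periodic lattice, and 1.63–1.69 on the level-4/5 hierarchical
benchmark graphs with analytic dimension ln 6/ln 3 ≈ 1.631. Origins in
components smaller than 8 nodes, or with fewer than 4 usable radii, return
NaN and are excluded (and counted) in per-node tables — this is how the
micellar regime, whose components have graph diameter ~2, is handled
deterministically.

## Multifractal spectra

`U_q(r) = Σ_i (M_i(r)/N)^q` is computed from the full mass matrix (one BFS
per node). `τ(q)` is the regression slope of `ln U_q` vs `ln r` rather than
a single-radius ratio: the two coincide for a perfect power law and the
slope is the stable estimator on finite graphs. The default `r` range is
2 up to the largest radius at which the *median* mass is below `N/2`
(excluding the trivial point and the plateau); the default `q` grid is
−5…5 in steps of 0.25, which covers sparse- and dense-node regimes without
overflow for graphs up to ~10⁴ nodes. `α = dτ/dq` uses central finite
differences (`numpy.gradient`), and `f(α) = qα − τ` holds pointwise by
construction. Homogeneous graphs collapse toward a point (ring width
< 10⁻¹³ in exact arithmetic); mixtures of architectures widen `w`.

## Benchmark fractal graphs

The hierarchical generator produces deterministic graphs of tunable
dimension `ln(b)/ln(1/f)` with integer `1/f = s ≥ 2` and `b ≥ s`. The
level-k unit chains `s` level-(k−1) units end-to-end (distances ×s per
level) and attaches the remaining `b − s` units as dangling branches,
round-robin over the backbone junctions (mass ×b per level). The BFS ball
of radius `s^j` around the left terminal (stored as
`graph.graph["origin"]`) contains the level-j prefix unit of ~`b^j` nodes,
so mass growth follows `r^{ln b/ln s}` with log-periodic oscillation — the
property the NFD estimator is validated against. Note that ball growth is
origin-dependent on these graphs (a deep junction sees a different
prefactor), so validation fixes the canonical origin. Constructions with
`b < s` are rejected: a connected graph cannot have ball dimension
below 1.

## Synthetic mesophases

The generators emulate the study conditions of a ~800-surfactant system:

- **Micellar**: 32 micelles × 25 molecules in a 22.04 nm cubic box. Heads
  on a 1.6 nm sphere (Fibonacci-uniform, randomly rotated), tails pointing
  inward; centre placement keeps micelles disconnected at 0.7 nm.
- **Hexagonal**: 4 z-periodic cylinders of 10 molecules/ring × 20 rings at
  0.5 nm ring spacing, axes on a staggered lattice. Head radius 1.4 nm
  (head plus two 0.47 nm tail beads), so terminal beads crowd ~0.46 nm off
  the axis into a dense molten core — volume-feasible at this loading and
  the reason a cylinder is graph-theoretically quasi-one-dimensional.
  Successive rings are staggered by half the angular spacing.
- **Lamellar**: 4 stacked bilayers of 10×10 molecules per leaflet at
  0.6 nm in-plane spacing, leaflets laterally staggered, opposing terminal
  beads 0.5 nm apart; 0.7 nm gaps between lamellae. A "bridge" is a
  tail-to-tail pair of molecules spanning a gap (a single 3-bead molecule
  cannot), modelling the transient inter-lamellar contacts that make the
  lamellar phase one well-connected graph; intact lamellae stay
  disconnected (closest inter-lamellar tail distance = gap + 0.94 nm).
- **Ideal solution**: uniformly random molecule centres and orientations
  with a 0.3 nm minimum site separation (rejection sampling with bounded
  restarts) — the non-aggregating baseline: flat RDF, P₂ ≈ 0.
- **FCC crystal** of single-site atoms and five **idealized aggregates**
  (planar 8-ring; 16-ring z-periodic cylinder; 224-molecule monolayer;
  interdigitated bilayer; 448-molecule tail-to-tail bilayer) for
  descriptor reference points.

All generators are bit-deterministic under an integer seed, wrap positions
into the box, and accept a small Gaussian jitter (default 0.03–0.04 nm)
standing in for thermal disorder.

What the generators do *not* emulate: liquid-like positional disorder
within aggregates, polydisperse aggregation numbers, molecular-scale
defects, counter-ions and explicit solvent, and any relaxation dynamics.
Passing tests therefore demonstrate that the descriptors recover the
architecture-level signatures (component structure, closeness bands,
quasi-1D vs 2D mass growth), not that they reproduce every feature of a
thermalised trajectory.

A known scale limitation: with 20 periodic rings the mean inter-ring hop
distance in a cylinder is exactly 5, which floors the modal closeness of a
200-node cylinder near 0.047 whenever its cross-section is compact. Longer
cylinders shift closeness down toward the ~0.035 peak reported for
thermalised hexagonal phases; at the 20-ring benchmark scale the modal
closeness sits ~35% above that value while the modal NFD (~1.2) is
reproduced. The two statistics cannot be moved independently at this
system size (looser cross-sections lower closeness but raise the apparent
dimension).

## Phase classification

Closeness thresholds 0.03 / 0.055 split molecules into micellar /
hexagonal / lamellar; values exactly at a boundary go to the middle
(hexagonal) class. The thresholds are system-size dependent — closeness
shrinks as graphs grow — and the defaults are calibrated for ~800-node
graphs. Phase fractions are computed per frame (always summing to 1) and
smoothed with a centered 25-point running average (truncated at the series
edges; clamped for shorter series). Coexistence is flagged as bimodality:
two local histogram maxima separated by a valley below 50% of the lower
peak — a documented heuristic standing in for visual inspection.
Transition location along a control parameter takes the maximum
finite-difference gradient of the smoothed mean-metric curve and declines
to report a location when the gradient is uniform within 10% (e.g. a
linear ramp).

## File formats and units

Coordinates are nm everywhere (GRO convention; MDAnalysis' Å are converted
on read/write). Only orthorhombic boxes are accepted; triclinic GRO box
lines are rejected with a clear message. Site roles map to atom names
HEA/TAI/TER/W/AR; GRO molecule identity comes from residue numbers, while
XYZ requires a sidecar selection file carrying per-site roles and molecule
ids (the box travels on the XYZ comment line as `Lx Ly Lz`, optionally
with `t=<ns>`). CSV columns are `mol_id,role,x,y,z` behind a
`# box Lx Ly Lz` header. Round trips preserve positions to the printed
precision (GRO: 3 decimals).

## Numerical conventions

- Histograms: 50 bins spanning the pooled min–max; constant data occupy a
  single bin. The reported "modal" value is the centre of the most
  probable bin.
- Quartile selections break ties by node id (stable sort) for determinism.
- Mass density uses bundled bead masses (head 59.13, middle tail 56.12,
  terminal tail 57.13, water bead 72.0, argon 39.948 g/mol), overridable
  per role.
- P₂ neighbours reuse the graph edge rule (min tail-site distance < 0.7 nm)
  so the orientational and topological analyses share one neighbourhood
  definition; the per-molecule value averages over neighbours, the system
  value over molecules with at least one neighbour.
- Random placement retries a jammed configuration from scratch (up to 50
  restarts) before declaring the density infeasible.

## Validation problem sizes

The shipped validation suite uses 200-node rings, 30×30 periodic lattices,
level-4 hierarchical graphs (~1300 nodes), 200 random graphs of up to 30
nodes against brute-force oracles, and 20 seeded replicates of each
~800-molecule mesophase — sizes chosen so the full suite runs in well
under a minute per module on a single CPU while leaving every scaling
regime (pre-saturation window ≥ 4 radii, ≥ 3 decades of q) represented.
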