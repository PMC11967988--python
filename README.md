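# phasegraph

Graph-theoretical descriptors of complex molecular phases.

Surfactant mesophases — micellar suspensions, hexagonally packed cylinders,
stacked lamellae — are hard to tell apart with classical order parameters:
energies and radial distribution functions change smoothly across their
phase transitions, and the nematic order parameter P₂ only senses local
orientation. `phasegraph` instead treats an aggregate as a **contact
graph**: one node per surfactant molecule, with an edge whenever any pair
of hydrophobic tail sites of two molecules lies within a cutoff distance
(0.7 nm, the first minimum of the tail-site RDF) under periodic boundary
conditions. Long-ranged graph descriptors computed on that graph separate
the mesophase architectures cleanly and track phase coexistence over time.

The package is aimed at people analysing particle configurations from
coarse-grained simulations (or any particle model), and ships synthetic
structure generators so every descriptor can be validated against known
geometry without running any molecular dynamics.

## Descriptors

For a graph with `N` nodes, `deg(v)` the degree and `d(v, u)` the
shortest-path distance:

- **Degree centrality** `C_d(v) = deg(v) / (N − 1)`.
- **Closeness centrality** (Wasserman–Faust form, well defined on
  disconnected graphs): with `n_v` the number of nodes reachable from `v`,
  `C_c(v) = [n_v / (N − 1)] · [n_v / Σ_u d(v, u)]`.
- **Betweenness centrality** `C_b(v) = Σ_{s<t} σ_st(v) / σ_st`, the fraction
  of shortest paths passing through `v`.
- **Clustering coefficient** `CC(v) = T(v) / (deg(v)(deg(v) − 1))` with
  `T(v)` the triangles through `v` (a `standard` convention with the usual
  factor 2 is also provided).
- **Node-based fractal dimension (NFD)**: the exponent `d` of
  `M(r) ~ r^d`, where `M(r)` counts the nodes within shortest-path radius
  `r` of an origin node (box-growing method).
- **Node-based multifractal analysis (NMFA)**: the partition function
  `U_q(r) = Σ_i (M_i(r)/N)^q` yields mass exponents `τ(q)`, and the
  Legendre transform `α = dτ/dq`, `f(α) = qα − τ(q)` gives the multifractal
  spectrum; its width `w = α_max − α_min` measures structural
  heterogeneity.
- **Classical baselines**: RDF `g(r)`, nematic order
  `P₂ = ⟨(3cos²θ − 1)/2⟩` over neighbouring molecular axes, mass density,
  and RDFs conditioned on descriptor quartiles.

Molecules with closeness below 0.03 are classified micellar, between 0.03
and 0.055 hexagonal, and above 0.055 lamellar (thresholds calibrated for
~800-molecule systems and configurable).

## Worked example

Generate a synthetic hexagonal phase (4 z-periodic cylinders, 800
molecules), build its contact graph and compute descriptors:

```python
import phasegraph as pg

config = pg.generate_hexagonal(seed=42)          # 800 molecules
graph = pg.build_contact_graph(config, cutoff=0.7)
print("components:", len(pg.connected_components(graph)))

cc = pg.closeness_centrality(graph)
print("mean closeness: %.4f" % cc.mean)
print("modal NFD: %.3f" % pg.metric_distribution(pg.nfd_table(graph)).mode)
print(pg.classify_nodes(cc).value_counts().to_dict())
```

prints

```
components: 4
mean closeness: 0.0476
modal NFD: 1.219
{'hexagonal': 800}
```

Each of the four cylinders is one connected component; the closeness values
fall in the hexagonal band (0.03–0.055) so all 800 molecules classify as
hexagonal, and the modal node-based fractal dimension of ~1.2 reflects the
quasi-one-dimensional architecture of a cylinder. The same pipeline on
`generate_micellar` yields mean closeness ≈ 0.014 (micellar band) and on
`generate_lamellar(bridge_count=2)` ≈ 0.11 (lamellar band).

The same operations are available from the shell:

```bash
phasegraph generate --kind hexagonal --seed 42 --out hex.gro
phasegraph metrics --input hex.gro --selection hex.gro.sel --out metrics.csv
phasegraph nfd     --input hex.gro --selection hex.gro.sel --out nfd.csv
phasegraph classify --input hex.gro --selection hex.gro.sel --out labels.csv
```

Formats: GRO, XYZ (box lengths on the comment line) and CSV, all in nm;
graphs export as edge lists or GraphML.

## Layout

- `synthetic_structures` — FCC crystal, random ideal solution, micelles,
  cylinders, lamellae (with holes/bridges), five idealized reference
  aggregates, and hierarchical benchmark graphs with known fractal
  dimension `ln(b)/ln(1/f)`.
- `trajectory_io` — GRO/XYZ/CSV configurations, trajectories, selection
  files.
- `graph_construction` — periodic contact graphs (k-d tree neighbour
  search), components, export.
- `centrality_descriptors` — the four node metrics plus histograms,
  running averages, normalization, correlations.
- `fractal` — mass functions, per-node NFD, NMFA spectra.
- `classical_order` — RDF, P₂, mass density, metric-conditioned RDFs.
- `phase_analysis` — closeness-threshold classification, phase fractions
  over time, coexistence detection, transition location.
- `cli` — `phasegraph` command with one subcommand per operation.

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
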