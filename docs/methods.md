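# Methods

## Problem and model

`forestconn` quantifies structural forest-habitat connectivity — connectivity
inferred from the physical arrangement of habitat, with no species movement
data — and how a land-consuming project changes it. Two models are combined.

**Circuit-theory current flow.** The land-cover raster is mapped to a
resistance surface and treated as an electrical network. Nodes are in-extent
cells; edges connect 8-neighbour cells. An orthogonal edge between cells with
resistances r_i, r_j has conductance g = 1/((r_i + r_j)/2); diagonal edges
divide that by √2 to account for the longer traversal (the standard
average-resistance raster convention). For a focal pair (s, t), unit current
is injected at s and extracted at t by solving the graph-Laplacian system
L·v = e_s − e_t with v(t) = 0; edge currents are g·Δv, and the per-cell
current density is half the sum of absolute incident edge currents (the
injected current, 1, at the two focal cells). "Pairwise mode" accumulates
this over all unordered focal pairs. Under unit injection, currents depend
only on resistance *ratios*, so the maps are invariant to uniform rescaling
of the resistance surface — a property the tests assert.

**Integral Index of Connectivity.** Habitat patches form a binary graph:
patches i, j are linked iff their edge-to-edge (boundary) distance is ≤ a
dispersal threshold d. With patch attribute a_i, minimum link count nl_ij
(BFS on the threshold graph; pairs in different components contribute 0), and
landscape area A_L,

    IIC = [ Σ_i Σ_j a_i a_j / (1 + nl_ij) ] / A_L²    (i = j included, nl_ii = 0)

A candidate reforestation cell is scored by "node to add": it joins the graph
as a new node with its own attribute, links and link counts are fully
recomputed, and varIIC = 100·(IIC_with − IIC_base)/IIC_base. Node addition
can only add non-negative terms and shorten paths, so varIIC ≥ 0 always;
an isolated candidate with attribute a contributes exactly
100·(a²/A_L²)/IIC_base. Both facts are used as test oracles.

## Pipeline assumptions and conventions

- **Five land-cover classes** (forest, grassland, cropland, waterbodies,
  unsuitable). Resistance profiles fix forest = 1 and unsuitable = 100 and
  sweep cropland/grassland/waterbodies over {10, 50, 90}: 3³ = 27 surfaces,
  ordered lexicographically by (cropland, grassland, waterbodies).
- **Tree-line mask.** Cells strictly above 3600 m a.s.l. become unsuitable;
  cells at exactly 3600 m keep their class ("above" is read as a strict
  inequality). The mask never converts unsuitable back.
- **Footprint burning** uses cell-centre containment (a cell converts iff its
  centre lies inside the polygon): unambiguous at any resolution, and
  idempotent.
- **Nearest-neighbour resampling** to a coarser grid; equidistant ties break
  toward the smaller source row, then column, for determinism.
- **Deforestation** between two dates means forest → cropland or unsuitable.
  Forest → grassland or waterbodies is not deforestation for this purpose
  (flooding and succession are not reforestation opportunities).
- **Focal nodes** are sampled uniformly (seeded, without replacement) from
  raster cells whose centre falls in the ring between the study-area boundary
  and the boundary dilated by the buffer width. The buffer defaults to 20% of
  the maximum extent length; a fixed width (e.g. 16 km) can be given instead.
  Focal cells may carry any land-cover class — the ring placement exists to
  keep the artificially high near-node currents outside the study area, not
  to select habitat. Pairs spanning disconnected components are skipped with
  a warning rather than failing the run.
- **Consensus.** Summing "only the maps that are not highly correlated" is
  implemented as near-duplicate removal: a greedy keep-first scan in profile
  order retains a map iff its Spearman ρ (average ranks for ties, computed
  over jointly valid cells) with every retained map is ≤ 0.99. The literal
  alternative — discarding every correlated map — can retain nothing. The sum
  is not normalised by the number of retained maps; percent change is
  unaffected whenever both scenarios retain equally many maps.
- **Percent change** is 100·(after − before)/before, signed and unclamped;
  0/0 cells are 0% and current-from-zero cells are masked undefined.
- **Hexagons.** Pointy-top regular hexagons of exactly 10 ha (edge
  s = √(2A/(3√3)) ≈ 196.19 m), anchored at the extent's lower-left corner.
  A hexagon is *forested* iff ≥ 99.9% of its pixels are stable forest (the
  tolerance absorbs rasterisation edge effects on "100%"), else *deforested*
  iff ≥ 10% of its pixels are deforested, else *other*. Adjacent forested
  hexagons merge into patches (connected components of the edge-adjacency
  graph); deforested cells never merge.
- **Patch attribute.** "Current density divided by patch area" is read as the
  summed after-scenario pixel current over the patch divided by its area
  (mean current density per m²); candidates use the identical formula, so
  patch and candidate attributes share one scale.
- **Percentile filter.** The 20th percentile (linear interpolation) is taken
  over the *deforested cells'* mean currents, not the whole map — the filter
  selects among deforested areas; retention is strictly above the cutoff.
- **Selection size** N = round-half-up(lost forest area / 10 ha); by default
  the lost area is the measured forest loss between the before and after
  scenarios. varIIC ties break toward the smaller candidate id. Rankings at
  different dispersal thresholds are independent; the overlap summary reports
  the percentage of selected cells chosen at 1, 2, … all thresholds.

## Numerical choices

- Sparse Laplacian solves use one SuperLU factorisation per connected
  component (grounding one node to remove the singularity), reused across
  all focal pairs; each pair is then a pair of triangular solves. Against a
  dense pseudoinverse oracle (`pinv(..., hermitian=True)`) voltages agree to
  < 1e-8 and Kirchhoff residuals are < 1e-8 at every node on 200 random
  graphs — in practice both are at machine precision.
- Link counts nl_ij come from unweighted shortest paths
  (`scipy.sparse.csgraph`); the brute-force test oracle is an explicit double
  loop with hand-written BFS, and agreement is required to 1e-12 relative.
- Hexagon vertices are computed trigonometrically; shared edges between
  neighbouring cells agree to ~1e-10 m, so adjacency is taken from the hex
  grid indices, not from geometric predicates on near-degenerate
  intersections.
- Raster I/O is ESRI ASCII grid (plain text, single band); vectors are
  GeoJSON. Inputs must already share one projected metric CRS; the tool
  refuses to reproject and fails loudly on CRS mismatch. NoData cells are
  excluded from the conductance graph, from Spearman vectors and from every
  zonal statistic.

## Synthetic landscapes

The generator emulates the structure the analysis assumes rather than any
real geography: thresholded Gaussian-smoothed noise gives a forest pattern
whose patch graininess is set by the smoothing length (`fragmentation`); a
meandering polyline rasterised at a configurable width is the river; the
elevation is a south–north linear gradient (default 200–4000 m) plus smooth
noise so the 3600 m mask is exercised; the project footprint is an elongated
rectangle centred on the river (a reservoir-like geometry) and guaranteed to
overlap forest and river cells; deforestation removes a clustered top
fraction of year-1 forest cells (default 4%), split 70/30 between cropland
and unsuitable. Defaults: 160×160 cells at 60 m, 60% forest, 50 focal nodes,
buffer = 20% of the extent. All randomness flows from one integer seed;
identical configurations are bit-identical.

What the generator does *not* emulate: terrain-driven hydrology, climate
layers, class-transition dynamics other than deforestation, spatial
autocorrelation structures of real land-cover products, and georeferencing
quirks (skewed/rotated grids). Tests passing on synthetic data therefore
demonstrate the correctness of the algorithms and the wiring of the
pipeline, not the realism of any particular ecological prediction.

The deterministic `pinch_fixture` — two forest blocks joined by a single
3-cell corridor in unsuitable terrain, with a footprint that burns exactly
the corridor — is the end-to-end scenario: current concentrates in the
corridor before, collapses by ~92% in the burned cells after (the residual
reflects the 1:100 resistance cap, so "complete loss" cannot reach exactly
−100%), losses propagate well beyond the footprint, and the top-ranked
reforestation candidate at every dispersal threshold lies on the severed
corridor.

## Problem sizes

The shipped test-suite and acceptance-script runs use deliberately compact
problems chosen to exercise every code path at interactive speed: pinch
scenarios of 30–60 cells a side with 5–8 focal nodes and the full 27-surface
ensemble, 200 random circuit graphs of ≤ 100 nodes, and 100 random patch
sets of ≤ 50 patches at three thresholds. Production-scale runs (hundreds of
thousands of cells, 50 focal nodes) use the same code; the per-surface
factorisation-reuse makes the 1 225 pairwise solves the dominant but
embarrassingly simple cost.

## Known limitations

- Pairwise mode only; advanced/one-to-all modes, short-circuit regions and
  omnidirectional (moving-window) connectivity are out of scope.
- Candidates are scored one at a time; the selected top-N set is not a joint
  optimum (no portfolio interactions), matching the node-to-add procedure.
- Binary IIC only; probabilistic indices (PC) are not implemented.
- No reprojection, cloud masking or more-than-two-date change analysis.
- Resistance values are dimensionless ordinal multipliers; absolute current
  densities have no physical unit and should be compared only within a run.
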