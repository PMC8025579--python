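# Methods

## The index

The Healthy Location Index is a rank-based composite. Its pipeline is
strictly ordinal: per-domain distances → ordinal ranks 1..N (ties broken
by ascending meshblock id) → unweighted rank sums per polarity side →
re-ranked → equal-count deciles (⌈10·r/N⌉) → three categories
(deciles 1–3 / 4–7 / 8–10) → nine goods–bads classes. Two consequences
are load-bearing and tested:

* **rank invariance** — any strictly increasing transform of one
  domain's distances leaves every output unchanged;
* **balance** — each domain's ranks are exactly a permutation of 1..N
  (so decile sizes differ by at most one), which is why strict ordinal
  ranking with an id tie-break is used instead of average or dense
  ranking.

Deciles are meshblock-count based, not population-weighted: the index
describes places, and the population enters only in the share summaries.
The ordering of the nine classes from healthiest to unhealthiest is fixed
at the extremes ("1–3" best, "3–1" worst); the middle order
(1–3, 1–2, 2–3, 1–1, 2–2, 3–3, 2–1, 3–2, 3–1) is this package's
convention for sorting output, not a substantive claim.

## Access metrics

**Facility domains.** Distance is measured along the road network from
the meshblock's population-weighted centroid to the nearest outlet. Both
endpoints are snapped to the nearest point on any edge (perpendicular
projection clamped to endpoints; ties broken by the smallest node-id
pair); edges are split at the snap offsets, and the straight-line access
legs are included in the total. Including the legs keeps the
facility-at-centroid identity exact (distance 0) and prevents free
teleportation onto the network. Batch computation subdivides each edge
at every snap point and runs one multi-source Dijkstra per domain
through a super-source wired to the facility snap nodes; this is exactly
equivalent to per-origin shortest paths and is cross-checked against a
pure-Python split-edge Dijkstra oracle in the tests. If a centroid
cannot reach any outlet of a domain (possible on disconnected
user-supplied networks; the generator always emits a connected graph),
the straight-line distance is substituted and the cell flagged
`euclidean_fallback`, so the table never has missing values.

**Green/blue space.** These are area phenomena without a meaningful
"entrance", so they are handled on a 50 m boolean presence raster: a
Euclidean distance transform gives each cell's distance to the nearest
covered cell (of the merged layer — per-feature medians were the other
possible reading; merged-layer nearest cover is adopted and documented
here), and a meshblock's access is the **median** of the values at cells
whose centres fall inside its polygon. A meshblock too small to contain
any cell centre takes the value of the cell containing its centroid.
Cell membership is centre-in-polygon throughout; cell (0,0) sits at the
window's lower-left corner and centres are at origin + (i+0.5)·50 m.

Distances are kept at full double precision internally and in the CSVs;
rounding to the 2 dp typically reported is presentation-only.

## Synthetic regions

The generator emulates a small national study region so that every
stage is testable without any data download. Defaults are the package's
study conditions.

* **Window**: square, area 0.25 km² per meshblock (n=500 → ~11.2 km
  side), a compromise between urban (~0.05 km²) and rural meshblock
  sizes.
* **Meshblocks**: Voronoi cells of jittered grid points, clipped to the
  window (mirror points keep every cell finite). Cells are convex, so
  the population-weighted centroid — the weighted mean of 6 dwelling
  points with a multinomial split of the population — is always inside.
  Populations are uniform on [60, 120]. How the census agency actually
  computes population-weighted centroids is not public; the
  weighted-mean-of-dwellings definition is this package's stand-in.
* **Deprivation**: a smooth field (diagonal ramp plus six small
  Gaussian bumps, amplitudes 0.02–0.07 of ~1.5 ramp range) evaluated at
  centroids and rank-cut into equal-count deciles. The field is
  deliberately *band-forming*: deprivation varies smoothly with wavy
  contours but forms no closed islands. An island of high deprivation
  inside an affluent area would inherit its neighbourhood's sparse
  facility provision, so island-forming fields blur the planted decile
  gradient that the generator is supposed to exhibit.
* **Urban/rural**: six classes assigned by local population-density
  quantiles (density = population within 0.12·side of the centroid);
  `urban_fraction` (default 0.7) sets the urban share, split 35/25/20/20
  across the four urban classes and 30/70 across the two rural ones.
* **Roads**: the full Delaunay triangulation over the centroids plus
  n/3 jittered Steiner points — a dense, connected, planar street mesh.
  Keeping every triangulation edge gives near-Euclidean routing with
  uniform detour factors (sparser prunings were tried and made detours
  erratic enough to blur the planted decile gradient). Every centroid is
  itself a node, so origin access legs are zero on synthetic regions.
  Edge length is Euclidean.
* **Facilities**: each domain draws `facilities_per_domain` points
  (default n/5 — provision scaling with settlement size) from a density
  proportional to exp(5.5·γ·(dep01 − 1)), where dep01 is the normalised
  deprivation field and γ = gradient_strength × domain multiplier
  (1.0 for the five 'bads', 0.4 for supermarkets and physical-activity
  facilities, 0 for fruit/veg). Sampling is two-stage stratified
  systematic — equal-weight row bands, equal-weight column strata within
  each band, one point per stratum with a small (0.05-stratum) jitter —
  i.e. a gently jittered density-warped lattice rather than an iid draw.
  Independent draws were tried first and rejected: their Poisson
  clumping noise exceeds the per-decile median steps, drowning the
  planted gradient the generator exists to exhibit. Finally each
  facility is moved to the nearest point on the road network, as
  commercial premises front onto streets; this also removes the
  facility-side access leg (another otherwise-dominant noise source)
  from every reported distance.
* **Rasters**: green cover is a union of scattered circular blobs
  (max(6, n/60) of them, radii 1.5–5% of the window side); blue cover is
  the ring of window-boundary cells (the "coastline") plus one interior
  lake. Resolution 50 m.
* **Determinism**: every layer draws from its own named substream of the
  single seed, so regeneration is bit-for-bit reproducible and adding
  one layer never perturbs another.

### What the generator does and does not emulate

It reproduces: equal-count deprivation deciles with spatial
autocorrelation, denser 'bads' in deprived areas (and the weaker
patterning of some 'goods'), connected road topology with detours,
contiguous green/blue cover including a coastline, and realistic
magnitudes of nearest-outlet distances (~0.4–2 km medians). It does not
emulate: real street topology or travel times, the extreme
urban/rural size contrast of real meshblocks, per-feature green-space
entrances, coastal geography beyond a boundary ring, or the empirical
uptick of distances in the most deprived decile that national data show
(a feature of real city centres, deliberately not planted — the
monotone-gradient checks therefore run over deciles 1–9). Passing tests
demonstrate correctness of the pipeline and recoverability of a planted
gradient, not calibration to any real country's magnitudes.

## Statistical summaries

* Median distances are computed per deprivation decile and overall,
  meshblock-weighted (each area counts once) since the table describes
  distances per area unit.
* The group-difference test is **Kruskal–Wallis** with the chi-square
  approximation (an optional seeded permutation p-value is available):
  a nonparametric test matches the ordinal framing and the skewed
  distance distributions. Its null calibration is verified empirically:
  over 100 zero-gradient regions the 5% rejection rate for each facility
  domain stays inside the binomial 99% band — at its conservative edge,
  because the near-lattice facility placement suppresses between-decile
  variance relative to an iid null; the test never rejects spuriously,
  which is the direction that matters for the gradient claims. The
  green/blue columns are
  excluded from that calibration check — raster proximity is a fixed
  spatial feature (the coastline ring especially), so it correlates with
  the spatial deprivation field even when facility placement is
  independent of deprivation, and its grid-quantised medians carry heavy
  ties; the independence null simply does not apply to those columns.
* Population shares per HLI class are population-weighted within each
  grouping level (overall, deprivation quintile = ⌈decile/2⌉, or
  urban/rural class) and sum to 100% over non-empty levels;
  zero-population meshblocks contribute nothing.
* The goods-vs-bads association is Spearman's ρ between the two
  composite ranks, overall and per quintile (undefined below 3
  meshblocks). Scatter plots overlay a rolling-median trend per
  quintile; the smoother is presentation-only and nothing downstream
  depends on it.

## Numerical choices

* Snap ties: smallest (u, v) node-id pair; rank ties: ascending
  meshblock id; both make every output deterministic.
* Zero-length sub-edges (coincident snap points) are stored as 1e-300 m
  so they survive sparse-matrix construction; parallel edges keep their
  minimum length.
* Degenerate inputs fail loudly: empty facility lists, all-zero dwelling
  weights, rasters with no covered cell, deciles requested for N < 10,
  non-finite distances (named by meshblock id). Region loading collects
  *all* invariant violations into one error rather than stopping at the
  first.
* Problem sizes used by the test suite and acceptance script — n=2000
  for gradient recovery, 100 regions of n=300 for null calibration,
  n=500 for structure/determinism, 100 meshblocks for full naive-oracle
  equivalence, 80-node networks for shortest-path cross-checks — are the
  package's chosen study sizes: large enough for ~200 meshblocks per
  decile (gradient), small enough that exhaustive oracles stay exact
  companions.

## Known limitations

* The window boundary is land's edge: meshblocks near it see facilities
  on one side only, inflating their distances slightly; the blue
  "coastline" makes this intentional but it remains an edge effect.
* The nine-class healthiness ordering beyond the two anchored extremes
  is a convention; analyses should treat the classes as nominal.
* With very small `facilities_per_domain` the planted gradient's decile
  medians become noisy; the monotone-gradient guarantee is stated for
  the default provision at n=2000.
* The empirical D10 uptick (most deprived decile slightly farther from
  outlets than D9) is not modelled.
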