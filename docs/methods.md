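# Methods

## Model

`pollinet` treats potential plant–pollinator interaction as co-occurrence
of suitable habitat. The inputs are per-species habitat-suitability
rasters on one shared north-up WGS84 grid of square cells. Each raster is
binarized — presence where suitability strictly exceeds a threshold —
and the presence layers of the two guilds are stacked. For a cell with
plant presence vector **p** ∈ {0,1}^P and pollinator presence vector
**a** ∈ {0,1}^A, the cell's incidence matrix is the outer product
B = **p a**ᵀ: every co-occurring pair is a potential link. Optionally the
matrix is intersected elementwise with a reference catalog of known
interactions (the metaweb), which can only remove links. Comparing the
matrices extracted from current and from scenario-projected range maps
yields, per cell, the species lost and gained, the links lost, and the
links gained (rewiring).

The model's assumptions are inherited from this construction: interaction
requires only spatial overlap at the grid resolution (no phenology, no
abundance, no behavior); binarization is meaningful at the chosen
threshold; and absence of suitable habitat implies absence of the species.
These are strong assumptions — the method quantifies the *spatial
opportunity* for interaction, not realized visitation.

## Key parameters

- **Binarization threshold** (default none; the conventional
  high-suitability cutoff is 0.6): presence iff suitability > threshold.
  The comparator is strict `>` because the high-suitability class is
  defined by values *exceeding* the cutoff; a `>=` variant is exposed
  (`inclusive=True`) since published maps do not always disambiguate.
  Raising the threshold can only shrink presence sets, so per-cell link
  counts are monotonically non-increasing in it.
- **Missing data**: a raster's NoData cells are "unknown", never "absent".
  A cell enters network extraction only if it is valid in *every* layer of
  *both* stacks; richness maps, which are descriptive, count valid layers
  only and leave a cell missing only when every layer is missing there.
  This prevents asymmetric missingness from masquerading as absence.
- **Alignment tolerance**: grids must agree within 1e-9 degrees in origin,
  cell size and shape. Nothing is ever resampled silently.
- **Metaweb modes**: `strict` (default) errors when a mapped species is
  absent from the catalog; `permissive` treats all its links as
  disallowed and logs it. Both are useful: strict catches id mismatches,
  permissive matches catalogs that are knowingly incomplete.
- **Coordinates**: per-cell files are named by cell-center latitude and
  longitude with 6 decimals; species axes are sorted lexicographically.
  Both choices exist to make outputs byte-stable across platforms and runs.

## Network metrics

All twelve indices are computed on the *active matrix* — the incidence
matrix with all-zero rows and columns removed — while the active species
counts are reported as the two "number of species" metrics and the dropped
counts are retained. Minimum sizes: the three nestedness indices need an
active matrix of at least 2×2; modularity needs ≥ 2 species and ≥ 1 link;
robustness needs ≥ 1 removable species. Below these a metric is "not
computable" (`None`), and batch means average only over networks where a
metric was computable, weighting cells equally.

- **Connectance, web asymmetry, links per species** are the standard
  ratios L/(P·A), (A−P)/(A+P), L/(P+A).
- **Linkage density** is the quantitative, diversity-weighted index: each
  species contributes its effective partner number 2^H weighted by its
  marginal total. For 0/1 matrices 2^H equals the degree, so the index
  reduces to (Σdᵢ² + Σdⱼ²)/(2L); the tests cross-check this reduction
  against an explicit-entropy oracle.
- **NODF** follows the decreasing-fill paired-overlap definition; pairs
  with equal fill contribute zero.
- **Weighted nestedness** implements a weighted-NODF variant whose pair
  rule requires strictly decreasing marginal totals and counts cells with
  0 < w_poor ≤ w_rich. On purely binary data this coincides with NODF,
  which is asserted in the tests and should be kept in mind when comparing
  against count-weighted indices, which are degenerate on binary input.
- **Nestedness temperature** packs rows and columns by descending marginal
  totals, scores every cell by its normalized anti-diagonal position
  s = (i+½)/P + (j+½)/A, takes the L lowest-scoring cells as the perfectly
  nested matrix of the observed fill, and sums squared normalized score
  distances from that boundary for presences outside it and absences
  inside it; the mean is scaled by the Atmar–Patterson constant
  100/0.04145 and clamped to [0, 100]. Packing *minimizes* disorder:
  arrangements differing only within marginal ties are enumerated for the
  coldest one (capped at 50 000 arrangements, beyond which an alternating
  marginal/content sort packs heuristically), which makes the value
  invariant to row/column permutations of the input. This is a simplified
  member of the published temperature family; bit-compatibility with any
  legacy program is not claimed, but the anchors hold exactly: any packed
  stair matrix scores 0, disorder scores hot.
- **Modularity** is Barber's bipartite Q maximized by label propagation:
  columns adopt the row label with the largest modularity gain (ties to
  the smallest label), rows likewise from columns — each half-sweep is
  exact coordinate ascent — followed by greedy merging of module pairs
  while Q improves, restarted from 10 seeded random initializations.
  On all fuzzed matrices with ≤ 8 species the heuristic attains the
  exhaustively enumerated optimum.
- **Robustness** removes species of one level in a given order (uniform
  random by default, 100 seeded replicates; degree-ascending and
  -descending orders are available since the removal order used in
  published tables is often unstated); species at the other level with no
  remaining partner go secondarily extinct, and R is the trapezoidal area
  under the survival curve from (0, 1) to (1, 0). Closed forms anchor the
  tests: a single link gives 0.5, a complete P×A web gives 1 − 1/(2S).

## SDM support

Occurrence thinning is a greedy prefix scan in input order: a point is
kept iff it lies at least the cutoff distance (haversine, Earth radius
6371.0 km; default 10 km) from every already-kept point. This is
deterministic and idempotent. Pseudo-absences are cell centers drawn
uniformly without replacement from usable cells containing no presence
point. AUC is the rank-based Mann–Whitney statistic with midrank ties.
IMAE is 1 − mean |prediction − label| with presence = 1 and
pseudo-absence = 0 (the error's operand convention is not standardized;
this one is documented rather than guessed silently). The continuous Boyce
index uses 101 overlapping windows of width one tenth of the combined
score range — the common continuous-Boyce defaults, since the metric's
parameters are rarely reported — drops windows with zero expected share,
and returns the Spearman correlation of P/E against the window midpoint,
or "not computable" when fewer than three windows survive.

## Synthetic landscapes

The generator emulates the *structure* of SDM output, not its ecology:
sum-of-Gaussian-bump suitability surfaces with seeded noise; block-shaped
random ranges covering ~25% of a 50×50 demo grid over a Chile-like
bounding box (lat −56..−17, lon −76..−66); random metawebs with a target
connectance of 0.3 (matching typical plant–pollinator catalogs) and a
guaranteed minimum degree of one; and future scenarios built by shifting
every range a whole number of cells with edge clipping, then deleting a
known fraction of presence cells at random. One global seed fans out to
per-species sub-seeds by a stable CRC-32 hash of the species id, so adding
a species never perturbs the others. Because the future maps are
constructed, their expected range changes are known (−100·c% for an
unclipped range contracted by c; −100% for a fully clipped shift), and the
pipeline's recovery of those values is what the end-to-end tests check.

What passing these tests does *not* show: real suitability surfaces have
spatial autocorrelation structure, range shapes, and threshold sensitivity
that blocks-plus-bumps do not reproduce; nothing here validates the SDMs
themselves, only the overlay-and-score machinery downstream of them.

## Numerical and design choices

- Percentage range change is undefined when a species has no current
  high-suitability cell; such species are reported as a separate
  "new range" count rather than an infinite percentage, and zero-change
  species join neither the increase nor the decrease group. Group standard
  deviations are population SDs.
- Species presence in a cell network is tracked by the extraction-time
  presence vector, not by nonzero link rows: a species whose every
  co-occurring partner is disallowed by the metaweb is "present but
  unlinked", so scenario diffs can separate species loss from link loss.
- Networks with zero links are omitted by default (`drop_empty`), which
  automates the manual pruning of interaction-free files; `--keep-empty`
  retains them.
- Label-propagation ties break toward the smallest label index;
  temperature packing ties are resolved by the exhaustive cold-search
  described above; trapezoidal integration is used for every
  extinction curve.
- Demo problem sizes (50×50 grid, 20+20 species; smaller in tests) were
  chosen so that every documented workflow runs in seconds while still
  producing four-digit network counts comparable in structure to real
  regional studies.

## Limitations

- Geographic WGS84 rasters with square cells only; no reprojection.
  The GeoTIFF layer is deliberately minimal (single band,
  ModelPixelScale/ModelTiepoint georeferencing, GDAL-style NoData).
- Binary interactions only: no visitation counts, no interaction
  strengths; the weighted-nestedness entry is the binary-degenerate
  variant described above.
- The temperature and modularity values are well-defined and reproducible
  but heuristic beyond small sizes (packing cap, label propagation);
  significance testing against null models is out of scope.
- Fitting distribution models, occurrence retrieval, and climate layers
  are upstream of this package.
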