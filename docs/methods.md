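# Methods

## Data model

An *occupation* is a dated stratigraphic unit at an archaeological site,
carrying: a unique ID; a cultural affiliation (one of the seven Early
Neolithic Western-Mediterranean archaeological cultures IMP, TyC, RPC, LCC,
VC, LCE, VE, or `NONE` for unaffiliated sites, which stay in networks but
are excluded from per-cultural-unit statistics); WGS84 coordinates; a
calibrated date range in years cal BP (`date_early ≥ date_late`, since BP
counts backwards); and membership in one or more of three time sequences.
The seven cultures group into three main cultural units — Impressa (IMP),
Cardial (TyC, RPC, LCC, VC), and Epicardial (LCE, VE).

Assemblage tables are occupations × traits, either non-negative integer
counts with positive row sums (pottery decorative techniques) or 0/1
presences (bead types).  Loading never drops rows: records with missing
coordinates or dates are kept and flagged in a load report.  Column naming
is config-driven so differently-labelled spreadsheets map onto the same
schema.

## Similarity

Brainerd-Robinson is computed on within-assemblage proportions and rescaled
to [0, 1] (classical statistic / 200): it is symmetric, bounded, invariant
to multiplying an assemblage's counts by a positive constant, and equals 1
exactly when the proportion vectors coincide.  Jaccard is the set ratio
|A∩B|/|A∪B|.  Degenerate inputs (zero row sum; two empty presence sets) are
errors, not silent 0s or 1s.  Cultural distance for the Mantel tests is
`D = 1 − S`, the simplest monotone transform; Mantel r is reported for
distance matrices, so positive r means "culturally farther when
geographically/chronologically farther".

## Threshold rule

The network threshold is the *largest observed edge weight* `t` such that
the graph with edges `{w ≥ t}` has a connected component of at least
`n − max_outliers` nodes.  With `max_outliers = 0` this equals the bottleneck
(minimum) edge weight of a maximum spanning tree of the complete similarity
graph; the implementation processes edges in descending weight through a
union-find, handling whole tie-groups at once, and is verified against both a
brute-force threshold scan and the MST bottleneck on random matrices.  Ties
at the threshold are inclusive (`≥`), and edge weights are never rescaled
after thresholding.  An explicit threshold override is supported so published
cut values can be imposed verbatim; resolved thresholds are always written to
the run's provenance file.

A consequence worth knowing: when one pair of cultures happens to be closer
in trait space than the others, the connectivity rule must lower `t` to
whatever weight bridges the *most separated* groups, and all of the closer
pair's between-edges flood in.  Label assortativity of the threshold network
is therefore a stable signature of planted cultural structure only when the
between-culture separations are roughly symmetric (as with disjoint
preferred-trait pools in presence mode), not for arbitrary Dirichlet-drawn
count profiles.

## Network statistics

* **Density** `2E / n(n−1)` over all nodes, isolates included.
* **Cluster coefficient**: global transitivity (3 × triangles / connected
  triples) on the binarized threshold graph is the default; the
  average-local variant (isolates and degree-1 nodes contributing 0) is
  available.  The metric name alone does not pin the variant, and the
  original study's choice could not be confirmed without its dataset, so the
  default follows the transitivity convention of the igraph-based network
  code that workflow family uses.
* **Strength** = sum of incident edge weights.
* **Eigenvector centrality** = leading eigenvector of the weighted adjacency
  matrix via power iteration (tolerance 1e-10, +I shift so bipartite
  structures cannot oscillate), scaled so the mean score is 1 — consistent
  with published maxima around 1.8–2.3 on networks of 32–46 nodes, which
  max-1 scaling could not produce.
* **Betweenness** on the binarized graph, unnormalized, with fractional
  splitting among equal-length shortest paths: published pottery scores are
  integers and ornament scores are thirds, which weighted-distance
  betweenness would essentially never produce.
* **Centralization** is Freeman's `Σ(c_max − c_i)` divided by the star-graph
  theoretical maximum for the same `n`: `(n−1)(n−2)` for strength (weights
  in [0, 1]), `(n−1)²(n−2)/2` for unnormalized betweenness, and
  `(n−1) − √(n−1)` for eigenvector scores rescaled to max 1.  Star graphs
  score 1 and regular graphs 0 under all three.  (Published graph-level
  betweenness values of order 1e-07 imply some much larger normalizing
  constant we could not reconstruct from the text; the Freeman convention is
  used and stated in the report metadata.)
* **Interval statistics**: min/mean/max with arg pairs of edge weight,
  great-circle km, and chronological years over retained edges only.
* **Similarity radius** per cultural unit: for each within-unit pair,
  geographic distance divided by similarity, aggregated min/mean/max over
  either all pairs (full scope) or only network-connected pairs (threshold
  scope).  Conventions: zero distance → radius 0; zero similarity at
  positive distance → +inf; an empty pair set (singleton unit) → the
  degenerate triple (min=+inf, mean=NaN, max=−inf).  Infinities are in-band:
  real tables print them.  The formula lives behind one function so an
  alternative (e.g. distance × dissimilarity) can be swapped without
  touching callers.

## Chronospatial distances

Great-circle distance uses the haversine formula with Earth radius
6371.0 km; against a WGS84 Vincenty oracle it agrees within 0.5% across the
Western Mediterranean latitudes the method targets (the spherical
approximation can drift to ~0.56% on long meridional near-equatorial paths,
outside this use case).

Chronological distance between date ranges defaults to the range-vector
Euclidean distance divided by √2, so two ranges rigidly shifted by `d` years
are `d` years apart; `gap` (0 if overlapping, else separation) and
`midpoint` variants are provided.  The published one-line description of
this distance is ambiguous and could not be calibrated without the study
data; the √2-scaled variant is the default because it degrades gracefully
to the rigid-shift interpretation.

Time sequences default to the study's three windows: 8000–7600, 7650–6800,
and 7000–6500 cal BP.  Membership is by date-range overlap — note the
windows themselves overlap, so a range can belong to several sequences —
and curated labels from a dataset always override date-derived assignment.
Consecutive-pair subsets (sequences 1–2, 2–3) feed the unchanged downstream
pipeline.

## Mantel tests

Mantel r is the Pearson correlation of strictly-lower-triangle vectors;
p-values come from simultaneous row/column permutation of one matrix,
one-tailed against the positive (isolation-by-distance) alternative, with
`p = (#{r_perm ≥ r_obs} + 1)/(B + 1)`.  The default `B = 1000` matches
published p floors of 1/1001.  The partial Mantel uses the
residual-permutation scheme: X and Y are each regressed on Z over the pair
vector, X's node labels are permuted and its residualization recomputed each
draw.  When a matrix is exactly explained by the covariate the residuals are
identically zero and the partial association is reported as r = 0, p = 1.
Threshold-matrix ("masked") variants correlate only the pairs connected in
the ASN; permutations relabel nodes and re-read values at the fixed mask
positions.  Calibration is checked empirically: on independent random
distance matrices (n = 30, 199 permutations) the rejection rate at α = 0.05
sits within [0.03, 0.07].

## Synthetic data

The generator emulates the study's data shape, not its content.  Defaults:
3 cultures × 12 occupations, 11 count traits, 200 counts per occupation,
culture trait profiles drawn from Dirichlet(0.5) (presence mode: 0/1 draws
with base rate 0.05 and +0.45 on a culture's preferred trait pool, traits
dealt round-robin); spatial scatter of sd 120 km around culture centers in
Liguria, Languedoc, and Catalonia; date ranges drawn inside a
culture-favoured time window (bias 0.6).  `distance_decay_strength` ∈ [0, 1]
blends each occupation's profile toward a west-east gradient between two
anchor profiles, planting isolation by distance; the default is 0.  A fixed
seed reproduces the dataset exactly.

Because cultures sit at distinct centers and favour distinct windows,
cultural distance correlates with geographic and chronological distance *by
construction* even without planted decay — as in the real archaeological
record, and a useful stress case for the partial tests.  What passing tests
on these data do **not** show: robustness to uneven sampling effort, to
assemblage-size variation across occupations, to trait evolution within a
culture's lifespan, or to spatially overlapping cultures — none of which the
generator models.

## Problem sizes used in validation

The property suite runs the threshold rule against brute force on 200 random
matrices (n ≤ 12), graph statistics against exhaustive path enumeration on
random graphs (n ≤ 10), similarity axioms on 1000 random pairs, Mantel
type-I error on 500 null replicates (n = 30, 199 permutations), power on 100
seeds of the default config with decay 0.5, and recovery on presence-mode
datasets at the study's 88-trait scale.  These sizes make the full suite and
the acceptance script each run in seconds on one CPU while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

* Published values that require the original spreadsheet (thresholds 0.44 /
  0.16, 231 / 217 edges, Table 1/3 centralities and Mantel r's) are encoded
  in a reproduction test tier that runs only when `data/s1_dataset.xlsx` is
  present; without it those numbers are unverified by this package.
* The betweenness-centralization normalizing constant of the original
  tables could not be reconstructed (see above).
* Radiocarbon calibration, basemap rendering, and typological coding are out
  of scope; dates are taken as given cal BP values and datasets as coded.
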