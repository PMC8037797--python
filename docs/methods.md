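# Methods

This note documents the models, conventions and numerical choices behind
`smlmtopo`, and what the synthetic-data experiments do and do not
demonstrate about real SMLM data.

## Data model

The unit of analysis is a localization table: one row per blink event with
frame, x/y position (nm), localization precision (nm) and channel. All
analyses are 2D (projections), with the origin at the field corner and y
increasing upward. The precision column defaults to 10 nm, the working
precision of the instrument class these tables come from; it is carried
through the pipeline but only the Gaussian rendering mode consumes it —
distances, clustering and persistence operate on the fitted coordinates.

## Synthetic point patterns

The simulators define the controlled conditions under which every
downstream method is validated:

- **Homogeneous**: exactly *n* i.i.d. uniform points in a rectangular
  field; the default field is 24,000 × 24,000 nm², the scale at which the
  reference pattern analyses were done.
- **Clustered**: N_Cl disc clusters of N_P points each, radius R; cluster
  centers uniform with each disc fully inside the field, points uniform in
  the disc (a truncated Gaussian profile is available as an option).
  Uniform-in-disc is the minimal reading of "circular clusters with
  homogeneously distributed points"; it makes the maximum intra-cluster
  distance ≤ 2R by construction, which is what the peak-width analysis
  estimates. Cluster centers are *not* given a minimum mutual separation;
  well-separated fixtures achieve separation statistically (10 clusters of
  R = 50 nm in a 24 µm field essentially never touch).
- **Mixture**: clustered pattern plus an independent uniform background;
  the clustered part is drawn from the same stream as the pure clustered
  pattern at the same seed, so the two agree point-for-point.
- **Two-channel nucleus**: circular heterochromatin domains (channel B)
  over a uniform background, and damage-focus clusters (channel A) placed
  either inside a domain (HC) or at least 400 nm outside every domain edge
  (nHC), with the flag recorded as ground truth. Defaults: 8,000 × 8,000 nm
  nucleus, 6 non-overlapping domains of radius 600 nm with 450 labeling
  points each over a 6,400-point background (≈5× in-domain density
  contrast, ≈9,000 channel-B events — a realistic per-nucleus yield),
  10 foci of radius 150 nm with 60 points each. These sizes keep expected
  inner-shell counts high enough (≈13 background vs ≈63 in-domain) for the
  density classifier to be tested meaningfully rather than trivially.

All generators take a single explicit integer seed (no global RNG state)
and are byte-for-byte reproducible.

What the simulations do **not** emulate: fluorophore re-blinking (one
molecule appearing as several correlated localizations), per-event
localization-error jitter, chromatic registration error between channels,
irregular nucleus boundaries, and non-circular domain shapes. Passing
recovery tests on these fixtures therefore shows the estimators are correct
under their stated model, not that real γH2AX/H3K9me3 data meet that model.

## Pairwise-distance analysis

Distances are computed in double precision for all ordered pairs (each
unordered pair contributes twice, the stated counting convention) and
binned into half-open [lo, hi) bins of uniform width, default 10 nm to
match the localization precision. A full-range histogram therefore sums to
exactly N(N−1). No Ripley-style edge correction is applied — the curves
are raw frequencies — so the linear-slope fit should be restricted to
distances well below the field size; the acceptance experiments fit over
0–2,000 nm in a 24,000 nm field (≤10%).

Peak metrics over a linear baseline: a bin is above threshold when its
excess over the baseline exceeds 3 local standard deviations, where the sd
of an ordered-pair count is √(2 × baseline) (the count is twice an
approximately Poisson unordered count; the factor 2 was confirmed
empirically against simulated homogeneous patterns, var/mean ≈ 2.0). The
peak is the first run of at least 2 contiguous above-threshold bins: a
genuine cluster peak is contiguous from small distances and many bins wide
(2R / bin width), while single-bin exceedances at large distances are
counting noise. Support width is the upper bin edge of that run, peak area
the summed positive excess within it. Both the 3σ multiplier and the
2-bin minimum run are tunables.

## Cluster detection and geometry

Detection uses density connectivity with the published parameter
vocabulary: neighborhood radius ε (the "minimum cluster radius") and core
threshold minPts (the "minimum number of cluster points", counting the
point itself). Cores within ε of each other join one cluster; border
events join the cluster of their lowest-index core neighbor — a
deterministic tie-break, unlike scan-order assignment. The maximum
point count and maximum extent ("maximum distance between the points
within the cluster") are post-hoc filters on the finished clusters, not
detection radii, since the neighborhood radius is specified separately.
Presets: `gammaH2AX_fig4` (200 nm, 46 points) for cluster counting,
`gammaH2AX_topology` (200 nm, 50) for barcode analysis, and `nucleosome`
(40 nm, >3 points, ≤100 points, ≤200 nm extent). There is deliberately no
hidden default preset.

Geometry is computed on the convex hull: area and centroid by the
surveyor's (shoelace) formula on the hull polygon, reported in µm² and nm;
cluster size as the RMS distance of hull vertices from that centroid.
"Distances of the points of the convex hull" admits a second reading —
pairwise vertex distances — which is available as `rms_mode="pairwise"`.
The hull was chosen over an ε-dilated footprint as the minimal assumption
for the cluster area. Degenerate hulls (collinear members) fall back to
the member mean and member-RMS and are flagged.

## Persistence

The filtration is defined operationally by sphere growth: vertices at
α = 0, an edge when two spheres of radius α touch (α = d/2), a triangle
when its three edges exist. Up to dimension 2 this is the Vietoris–Rips
complex at scale 2α and is the default backend. The alpha-complex backend
(Delaunay triangulation; triangle value = circumradius, edge value =
half-length for Gabriel edges else the smallest incident-triangle value)
gives the construction typically used for whole-nucleus clouds, where the
Rips complex would be infeasibly large; both backends parameterize by the
sphere *radius* α. Duplicate points are merged with a warning before
filtration (zero-length edges would only add trivial bars).

Dimension-0 persistence is computed by union-find over the α-sorted edges:
all components are born at 0, each merging edge kills one (the
higher-index representative — a deterministic resolution of the elder rule
when all births tie), and exactly one component per connected set survives
to infinity. Dimension-1 uses standard Z2 boundary-matrix reduction of the
triangle columns, with columns held as integer bitsets. Rips filtrations
are truncated at half the enclosing radius (min over points of the max
distance to any other point): beyond that scale the complex is a cone, so
the truncation provably loses no hole. An exhaustive textbook reduction of
the full, uncut filtration serves as the test oracle; the two agree
exactly on all ≤8-point fixtures.

Barcode post-processing mirrors the whole-nucleus protocol: endpoints
rounded to two decimals and bars whose rounded birth equals their rounded
death pruned. The rounding unit is µm (two decimals ⇒ 20 nm granularity at
the edge scale); rounding nm-scale values to two decimals would prune
nothing, so the µm reading is adopted and is configurable. Endpoint
histograms use death values only, are normalized per nucleus and per
dimension, and are averaged unweighted across nuclei; nuclei with no
finite bar in a dimension are skipped for that dimension and counted.
Optional seeded uniform subsampling is available for very large clouds.

## Barcode similarity and HC/nHC classification

Interval Jaccard: intersection length over union length; identical
degenerate bars define 1. Barcode similarity in a dimension solves the
maximum-weight bipartite assignment (Hungarian algorithm) on the interval
Jaccard weights and divides the matched total by the larger bar count, so
surplus bars penalize; this reduces to the stated 0/1 endpoints for
identical and disjoint barcodes. An alternative mean-of-best-match scoring
is behind `matching="best"`. Before comparison, endpoints are divided by
the barcode's scale reference (default: largest finite death), making the
comparison scale-invariant; normalization can be disabled. Two barcodes
both empty in a dimension score 1 (identical emptiness) and the event is
logged. The overall similarity is the mean of the dimension-0 and
dimension-1 values.

HC/nHC classification: concentric shells (default 10 shells of 50 nm; the
inner 4, i.e. 200 nm — the cluster-radius scale — form the decision
region) are centered on each cluster's shoelace centroid; the cluster is
HC when the heterochromatin point density over the inner region is at
least the threshold, by default the nucleus-wide mean density of the
heterochromatin channel. Shell geometry and threshold are explicit
interpretations (the primary sources defer them to earlier work) and are
fully configurable. Heatmap block summaries (mean HC–HC, nHC–nHC, HC–nHC,
excluding the diagonal) feed the second-generation averages; no
statistical testing of block differences is performed.

## Problem sizes and determinism

The validation experiments use desk-scale problems chosen to exercise the
estimators well inside their operating regime: 20 independent seeds for
each recovery experiment; 2,000–4,000 points for slope scaling; 10 × 100
points for cluster recovery; ≤8-point fixtures for the exhaustive
persistence oracle (the full boundary matrix grows combinatorially);
two-channel nuclei of ≈9,900 events. Every stochastic step takes an
explicit seed, and the pipeline embeds the configuration hash and seed in
its report, so identical configurations reproduce identical outputs.

## Known limitations

- 2D only; no 3D filtrations or clustering.
- No correction for re-blinking overcounting; apparent cluster statistics
  on real data conflate molecules and localizations.
- Raw distance frequencies rather than edge-corrected Ripley K/L or
  pair-correlation estimates; quantitative slope comparisons are only
  valid between patterns in the same field geometry.
- Dimension-2 homology (voids) and persistence images/landscapes are out
  of scope; so are bottleneck/Wasserstein barcode distances.
- The Rips backend is quadratic in points (cubic in triangles); use the
  alpha backend or subsampling beyond a few hundred points per object.
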