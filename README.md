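# smlmtopo

Spatial statistics and persistent-homology topology for single-molecule
localization microscopy (SMLM) point clouds.

SMLM does not produce images in the classical sense: it produces a table of
localizations — one row per fluorophore blink, localized to ~10 nm — so the
natural description of nuclear nanostructures (DNA-damage repair foci,
heterochromatin domains, nucleosome clusters) is a 2D point pattern, and the
natural analyses are point-pattern statistics and topology. `smlmtopo` is a
toolbox for that workflow, aimed at microscopists and image analysts working
with localization tables:

- **Simulation** of synthetic localization data with known ground truth:
  homogeneous random fields, circular clusters parameterized by
  (N_Cl, N_P, R) — number of clusters, points per cluster, cluster radius —
  cluster + background mixtures, and two-channel "nuclei" with
  heterochromatin domains and damage-focus clusters.
- **Pairwise-distance (Ripley-type) analysis**: histograms of all *ordered*
  pairwise distances (each pair counted twice). A homogeneous pattern gives
  a linearly rising curve whose slope scales with N²; clustering adds a
  small-distance peak whose support width estimates the cluster diameter 2R
  and whose area counts the in-cluster pair surplus; two-component patterns
  decompose exactly into within-A + within-B + cross-term histograms.
- **Density-based nano-cluster detection** (DBSCAN semantics: neighborhood
  radius ε, core threshold minPts, optional maximum size/extent filters,
  published presets for γH2AX and nucleosome clusters) with convex-hull
  geometry: surveyor's (shoelace) centroid and area, RMS cluster size.
- **Persistence barcodes**: grow a disc of radius α around every point;
  points connect when their discs touch (α = d/2), triangles fill when
  their three edges exist. Dimension-0 bars track connected components,
  dimension-1 bars track holes; Betti numbers B0(α), B1(α) count features
  alive at α. Backends: Vietoris–Rips restricted to dimension ≤ 2
  (default) and a 2D alpha complex for large whole-nucleus clouds.
- **Jaccard barcode similarity**: bars compared by interval
  intersection-over-union (1 = identical, 0 = disjoint), barcodes by
  maximum-weight one-to-one bar matching, dimensions averaged into an
  overall similarity; all-vs-all heatmaps with clusters ordered
  heterochromatin-associated (HC) first, and second-generation heatmaps
  averaging the block summaries per condition.
- **HC/nHC classification** of damage clusters from the heterochromatin
  point density in concentric shells around each cluster center.

## Worked example

```python
from smlmtopo import (ClusterPatternSpec, FieldSpec, ClusterCriteria,
                      simulate_clustered, distance_histogram, peak_metrics,
                      detect_clusters, barcode, overall_similarity,
                      fraction_clustered)

field = FieldSpec(24_000.0, 24_000.0)                 # 24 x 24 um^2
spec = ClusterPatternSpec(n_clusters=10, points_per_cluster=100, radius=50.0)
table, labels = simulate_clustered(spec, field, seed=1)

hist = distance_histogram(table, bin_width=10.0, d_max=3000.0)
peak = peak_metrics(hist, baseline=None)
clusters = detect_clusters(table, ClusterCriteria(200.0, 46))
bc_a, bc_b = barcode(clusters[0].points), barcode(clusters[1].points)
```

Output:

```text
peak support width: 100 nm (cluster diameter 2R = 100 nm)
clusters detected: 10
fraction of events clustered: 100.0%
first cluster: 100 points, area 0.0066 um^2, RMS size 47.0 nm
bars (components/holes): 100/22
overall Jaccard similarity of clusters 0 and 1: 0.652
```

The distance-histogram peak ends at 100 nm — the diameter of the simulated
discs — and the detector recovers exactly the 10 simulated clusters with
every event assigned. Each 100-point cluster yields 100 component bars (one
per point, merging as α grows) and 22 hole bars; after scale normalization,
two clusters drawn from the same generating process score an overall
Jaccard similarity of 0.65.

## Command line

```bash
smlmtopo simulate --n-clusters 10 --points-per-cluster 100 --radius 50 \
         --seed 1 --out locs.csv
smlmtopo distances locs.csv --bin-width 10 --out hist.csv
smlmtopo cluster locs.csv --preset gammaH2AX_fig4 --out clusters.csv
smlmtopo topology locs.csv --backend alpha --out barcode.csv
smlmtopo compare barcode.csv barcode.csv --measure overall --out heatmap.csv
smlmtopo pipeline --seed 1 --out run/      # full two-channel analysis
```

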