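"""Density-based nano-cluster detection and cluster geometry.

Clusters are detected by density connectivity (DBSCAN semantics): a core
event has at least ``min_points`` events (itself included) within the
neighborhood radius; cores within the radius of each other connect into one
cluster; a non-core event within the radius of a core joins that core's
cluster (ties broken toward the lowest-index core, deterministically).
Clusters violating an optional maximum point count or maximum extent
(convex-hull diameter) are discarded afterwards, so every reported cluster
satisfies all four criteria.

Two named presets mirror the published parameter sets for γH2AX repair-focus
nano-clusters (radius 200 nm; 46 points for dose/kinetics counting, 50 for
topological analysis) and for nucleosome (H2B) clusters (radius 40 nm, more
than 3 points, at most 100 points, extent at most 200 nm).

Cluster geometry uses the convex hull: the centroid via the surveyor's
(shoelace) polygon formula, the area as the shoelace hull area in µm², and
the size as the RMS distance of the hull vertices from that centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError
from sklearn.neighbors import NearestNeighbors

from .localizations import LocalizationTable

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class ClusterCriteria:
    """Detection criteria: neighborhood radius (nm), minimum number of
    member events, optional maximum count and maximum extent (nm)."""

    neighborhood_radius: float
    min_points: int
    max_points: int | None = None
    max_extent: float | None = None

    def __post_init__(self):
        if self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.max_points is not None and self.max_points < self.min_points:
            raise ValueError("max_points must be >= min_points")
        if self.max_extent is not None and self.max_extent <= 0:
            raise ValueError("max_extent must be positive")


#: Published parameter presets.
PRESETS: dict[str, ClusterCriteria] = {
    # γH2AX nano-cluster counting vs dose / repair time
    "gammaH2AX_fig4": ClusterCriteria(200.0, 46),
    # γH2AX clusters used for topological (barcode) analysis
    "gammaH2AX_topology": ClusterCriteria(200.0, 50),
    # nucleosome (H2B) clusters: >3 points in r=40 nm, <=100 points,
    # <=200 nm maximal mutual distance
    "nucleosome": ClusterCriteria(40.0, 4, 100, 200.0),
}


@dataclass
class Cluster:
    """One detected cluster: member rows of the source table, convex-hull
    vertices (nm), shoelace centroid (nm), hull area (µm²), RMS size (nm),
    and an optional heterochromatin-association label."""

    members: np.ndarray
    points: np.ndarray                      # (m, 2) member coordinates, nm
    hull_vertices: np.ndarray               # (h, 2) ccw hull polygon, nm
    centroid: tuple[float, float]
    area_um2: float
    rms_nm: float
    degenerate: bool = False
    hc_label: str | None = None             # "HC" | "nHC" | None

    @property
    def n_points(self) -> int:
        return len(self.members)

    @property
    def extent_nm(self) -> float:
        """Hull diameter: maximum pairwise distance between members."""
        pts = self.hull_vertices if len(self.hull_vertices) >= 2 else self.points
        if len(pts) < 2:
            return 0.0
        from scipy.spatial.distance import pdist
        return float(pdist(pts).max())


def shoelace_area_centroid(vertices: np.ndarray):
    """Signed shoelace area and polygon centroid of an ordered polygon.

    Returns ``(area, (cx, cy))`` with area >= 0.  Degenerate polygons
    (fewer than 3 vertices, or zero area) return area 0 and the vertex mean.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0, tuple(v.mean(axis=0)) if len(v) else (np.nan, np.nan)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a2 = cross.sum()                        # twice the signed area
    if a2 == 0.0:
        return 0.0, tuple(v.mean(axis=0))
    cx = ((x + xn) * cross).sum() / (3.0 * a2)
    cy = ((y + yn) * cross).sum() / (3.0 * a2)
    return abs(a2) / 2.0, (float(cx), float(cy))


def _hull(points: np.ndarray):
    """Convex hull vertices (ccw) or None when degenerate/collinear."""
    if len(points) < 3:
        return None
    try:
        h = ConvexHull(points)
    except QhullError:
        return None
    return points[h.vertices]


def _make_cluster(members: np.ndarray, xy: np.ndarray,
                  rms_mode: str = "vertex") -> Cluster:
    pts = xy[members]
    hull = _hull(pts)
    if hull is None:
        centroid = tuple(pts.mean(axis=0))
        rms = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))) \
            if len(pts) else 0.0
        return Cluster(members, pts, pts[:0], centroid, 0.0, rms,
                       degenerate=True)
    area_nm2, centroid = shoelace_area_centroid(hull)
    if rms_mode == "vertex":
        d2 = np.sum((hull - centroid) ** 2, axis=1)
    elif rms_mode == "pairwise":
        from scipy.spatial.distance import pdist
        d2 = pdist(hull) ** 2
    else:
        raise ValueError("rms_mode must be 'vertex' or 'pairwise'")
    rms = float(np.sqrt(np.mean(d2)))
    return Cluster(members, pts, hull, centroid, area_nm2 / NM2_PER_UM2, rms)


def detect_clusters(points, criteria: ClusterCriteria | str,
                    *, rms_mode: str = "vertex") -> list[Cluster]:
    """Detect density-connected clusters satisfying ``criteria``.

    ``criteria`` may be a :class:`ClusterCriteria` or a preset name.
    Returns clusters ordered by their lowest member index.  An empty input
    yields an empty list.  ``rms_mode`` selects the RMS-size convention:
    hull-vertex-to-centroid distances (default) or pairwise hull-vertex
    distances.
    """
    if isinstance(criteria, str):
        criteria = PRESETS[criteria]
    xy = _as_xy(points)
    n = len(xy)
    if n == 0:
        return []
    eps, min_pts = criteria.neighborhood_radius, criteria.min_points
    nn = NearestNeighbors(radius=eps).fit(xy)
    neigh = nn.radius_neighbors(xy, return_distance=False)
    counts = np.fromiter((len(a) for a in neigh), dtype=int, count=n)
    core = counts >= min_pts            # neighborhoods include the point itself
    core_idx = np.nonzero(core)[0]
    if core_idx.size == 0:
        return []
    # density-connect the cores
    pos = -np.ones(n, dtype=int)
    pos[core_idx] = np.arange(core_idx.size)
    rows, cols = [], []
    for i in core_idx:
        cnb = [j for j in neigh[i] if core[j]]
        rows.extend([pos[i]] * len(cnb))
        cols.extend(pos[j] for j in cnb)
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(core_idx.size, core_idx.size))
    _, comp = connected_components(graph, directed=False)
    labels = -np.ones(n, dtype=int)
    labels[core_idx] = comp
    # border events join the cluster of their lowest-index core neighbor
    for i in np.nonzero(~core)[0]:
        cnb = [j for j in neigh[i] if core[j]]
        if cnb:
            labels[i] = labels[min(cnb)]

    clusters = []
    for lab in np.unique(labels[labels >= 0]):
        members = np.nonzero(labels == lab)[0]
        if len(members) < min_pts:
            continue
        if criteria.max_points is not None and len(members) > criteria.max_points:
            continue
        cl = _make_cluster(members, xy, rms_mode)
        if criteria.max_extent is not None and cl.extent_nm > criteria.max_extent:
            continue
        clusters.append(cl)
    clusters.sort(key=lambda c: int(c.members[0]))
    return clusters


def _as_xy(points) -> np.ndarray:
    if isinstance(points, LocalizationTable):
        return points.xy
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected (n, 2) coordinates or a LocalizationTable")
    return xy


def cluster_centroid(cluster: Cluster) -> tuple[float, float]:
    """Surveyor's-formula centroid of the cluster's convex hull (nm)."""
    return cluster.centroid


def cluster_area(cluster: Cluster) -> float:
    """Shoelace area of the convex hull, µm² (0 for degenerate hulls)."""
    return cluster.area_um2


def cluster_size_rms(cluster: Cluster) -> float:
    """RMS hull-vertex-to-centroid distance (nm); member RMS if degenerate."""
    return cluster.rms_nm


def qc_filter_cells(tables, min_signals: int = 10_000,
                    max_signals: int = 50_000) -> list:
    """Keep per-cell tables whose event count lies in [min, max].

    The default window reproduces the 10,000–50,000 signals-per-cell
    selection applied before nucleosome cluster statistics.
    """
    if min_signals <= 0 or max_signals < min_signals:
        raise ValueError("require 0 < min_signals <= max_signals")
    return [t for t in tables if min_signals <= len(t) <= max_signals]


def fraction_clustered(points, clusters) -> float:
    """Percentage of events that belong to any detected cluster."""
    n = len(points)
    if n == 0:
        raise ValueError("fraction_clustered undefined for an empty table")
    member = np.zeros(n, dtype=bool)
    for c in clusters:
        member[c.members] = True
    return 100.0 * member.sum() / n


def clusters_per_cell(tables, criteria) -> dict:
    """Per-cell cluster counts with a boxplot-style summary.

    Returns ``{"counts", "median", "q1", "q3", "mean", "sd",
    "whisker_lo", "whisker_hi"}`` where the whiskers are mean ± 2 SD.
    """
    counts = np.array([len(detect_clusters(t, criteria)) for t in tables],
                      dtype=float)
    if counts.size == 0:
        return {"counts": counts, "median": np.nan, "q1": np.nan, "q3": np.nan,
                "mean": np.nan, "sd": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan}
    mean, sd = float(counts.mean()), float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return {"counts": counts,
            "median": float(np.median(counts)),
            "q1": float(np.percentile(counts, 25)),
            "q3": float(np.percentile(counts, 75)),
            "mean": mean, "sd": sd,
            "whisker_lo": mean - 2 * sd, "whisker_hi": mean + 2 * sd}


def write_cluster_table(clusters, path, *, sep=",") -> None:
    """Export `cluster_id,n_points,centroid_x_nm,centroid_y_nm,area_um2,
    rms_nm,hc_label` as delimited text."""
    import pandas as pd
    rows = [{"cluster_id": i, "n_points": c.n_points,
             "centroid_x_nm": c.centroid[0], "centroid_y_nm": c.centroid[1],
             "area_um2": c.area_um2, "rms_nm": c.rms_nm,
             "hc_label": c.hc_label or ""} for i, c in enumerate(clusters)]
    pd.DataFrame(rows, columns=["cluster_id", "n_points", "centroid_x_nm",
                                "centroid_y_nm", "area_um2", "rms_nm",
                                "hc_label"]).to_csv(path, sep=sep, index=False)
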