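"""Ripley-type pairwise-distance frequency analysis.

For a point pattern the frequencies of all *ordered* pairwise distances
(each unordered pair counted twice, X→Y and Y→X) carry the pattern's spatial
structure: a homogeneous random pattern gives a linearly rising curve at
small distances (shell area grows linearly with radius) whose slope scales
with N²; clustered points add a peak at small distances whose support width
approximates the cluster diameter 2R and whose area counts the in-cluster
pair surplus (∝ N_Cl · N_P²); a cluster+background mixture decomposes
exactly into within-cluster, within-background and cross-term histograms.

No edge correction is applied — these are raw distance frequencies, not
Ripley's K — so slope fits should be restricted to distances well below the
field size (default guidance: <= 10% of the field width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy import stats

from .localizations import LocalizationTable

#: Default bin width, nm: matches the ~10 nm localization precision.
DEFAULT_BIN_WIDTH_NM = 10.0


def _as_xy(points) -> np.ndarray:
    if isinstance(points, LocalizationTable):
        return points.xy
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array or LocalizationTable")
    return xy


@dataclass
class DistanceHistogram:
    """Binned ordered-pair distance frequencies.

    ``counts[k]`` is the number of ordered pairs (i, j), i != j, with
    distance in the half-open bin ``[bin_edges[k], bin_edges[k+1])``.  When
    the bins cover [0, field diagonal], ``counts.sum() == n_points *
    (n_points - 1)`` exactly.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_points: int
    field_area: float | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def __add__(self, other: "DistanceHistogram") -> "DistanceHistogram":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("histograms are on different bin grids")
        return DistanceHistogram(self.bin_edges, self.counts + other.counts,
                                 self.n_points + other.n_points, self.field_area)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "count": self.counts})


@dataclass
class PeakMetrics:
    """Cluster-peak summary of a distance histogram: the support width of
    the above-baseline excess (≈ cluster diameter), the summed excess counts
    (∝ points-per-cluster² × number of clusters), and the excess mode."""

    peak_support_width: float
    peak_area: float
    peak_mode: float


def _edges(bin_width: float, d_max: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    n_bins = int(np.ceil(d_max / bin_width))
    return bin_width * np.arange(n_bins + 1)


def distance_histogram(points, bin_width: float = DEFAULT_BIN_WIDTH_NM,
                       d_max: float | None = None) -> DistanceHistogram:
    """Histogram of all ordered pairwise distances.

    Each unordered pair {X, Y} contributes two counts (X→Y and Y→X);
    self-distances are excluded.  Bins are half-open ``[lo, hi)`` of uniform
    width.  ``d_max`` defaults to the observed maximum distance (so the
    histogram is total: counts sum to N(N-1)).  Fewer than two points give
    an all-zero histogram.
    """
    xy = _as_xy(points)
    n = len(xy)
    area = None
    if isinstance(points, LocalizationTable):
        fld = points.meta.get("field")
        area = getattr(fld, "area", None)
    if n < 2:
        edges = _edges(bin_width, d_max if d_max else bin_width)
        return DistanceHistogram(edges, np.zeros(len(edges) - 1, dtype=np.int64),
                                 n, area)
    d = pdist(xy)
    if d_max is None:
        d_max = float(d.max()) + bin_width  # ensure the max falls in a bin
    edges = _edges(bin_width, d_max)
    counts, _ = np.histogram(d[d < edges[-1]], bins=edges)
    return DistanceHistogram(edges, 2 * counts.astype(np.int64), n, area)


def fit_linear_slope(hist: DistanceHistogram,
                     fit_range: tuple[float, float]) -> float:
    """Least-squares slope (counts per nm) of counts vs bin center over
    ``fit_range``.  The range should sit in the small-distance regime
    (≲ 10% of the field size) where boundary effects are negligible."""
    lo, hi = fit_range
    if hi <= lo:
        raise ValueError("empty fit range")
    c = hist.bin_centers
    sel = (c >= lo) & (c <= hi)
    if sel.sum() < 2:
        raise ValueError("fit range covers fewer than two bins")
    y = hist.counts[sel]
    if not np.any(y):
        return 0.0
    res = stats.linregress(c[sel], y.astype(float))
    return float(res.slope)


def peak_metrics(hist: DistanceHistogram, baseline,
                 *, excess_sigma: float = 3.0, min_run: int = 2) -> PeakMetrics:
    """Cluster-peak support width, area and mode over a linear baseline.

    ``baseline`` is the expected background count per bin: a scalar slope
    (counts per nm, expanded as slope × bin center), a ``(slope, intercept)``
    pair, an array of per-bin counts, or None/0 for a background-free
    pattern.  A bin is above the peak threshold when its excess exceeds
    ``excess_sigma`` × the baseline's local counting standard deviation:
    ordered-pair counts are twice an approximately Poisson unordered-pair
    count, so the sd is ``sqrt(2 × baseline)`` (floored at one unordered
    count).  The cluster peak is the first run of at least ``min_run``
    contiguous above-threshold bins scanning up from zero distance
    (in-cluster distances fill every bin up to the cluster diameter, so a
    genuine peak is contiguous and many bins wide; isolated single-bin
    exceedances are counting noise): the support width is the upper edge of
    that run, the area the summed positive excess within it, and the mode
    the center of its maximum-excess bin.  No qualifying run returns zeros.
    """
    centers = hist.bin_centers
    if baseline is None:
        base = np.zeros_like(centers)
    else:
        b = np.asarray(baseline, dtype=float)
        if b.ndim == 0:
            base = b * centers
        elif b.shape == (2,) and b.shape != centers.shape:
            base = b[0] * centers + b[1]
        elif b.shape == centers.shape:
            base = b
        else:
            raise ValueError("baseline must be a slope, (slope, intercept) "
                             "or a per-bin array")
    excess = hist.counts.astype(float) - base
    thresh = excess_sigma * np.sqrt(2.0 * np.maximum(base, 1.0))
    above = excess > thresh
    first = None
    k = 0
    while k < len(above):
        if above[k]:
            end = k
            while end + 1 < len(above) and above[end + 1]:
                end += 1
            if end - k + 1 >= min_run:
                first, last = k, end
                break
            k = end + 1
        else:
            k += 1
    if first is None:
        return PeakMetrics(0.0, 0.0, 0.0)
    width = float(hist.bin_edges[last + 1])
    region = excess[first:last + 1]
    area = float(np.sum(region[region > 0]))
    mode = float(centers[first + int(np.argmax(region))])
    return PeakMetrics(width, area, mode)


def decompose_two_sets(points_a, points_b,
                       bin_width: float = DEFAULT_BIN_WIDTH_NM,
                       d_max: float | None = None) -> dict:
    """Two-component decomposition of the pooled-distance histogram.

    Returns ``{"within_A", "within_B", "cross", "pooled"}`` on a common bin
    grid.  Additivity is exact: pooled = within_A + within_B + cross,
    bin-by-bin — the cross term holds the ordered A↔B distances.
    """
    xa, xb = _as_xy(points_a), _as_xy(points_b)
    pooled_xy = np.vstack([xa, xb])
    if d_max is None:
        d_max = (float(pdist(pooled_xy).max()) + bin_width
                 if len(pooled_xy) >= 2 else bin_width)
    edges = _edges(bin_width, d_max)

    def _hist(xy):
        if len(xy) < 2:
            return DistanceHistogram(edges, np.zeros(len(edges) - 1, np.int64),
                                     len(xy))
        d = pdist(xy)
        c, _ = np.histogram(d[d < edges[-1]], bins=edges)
        return DistanceHistogram(edges, 2 * c.astype(np.int64), len(xy))

    within_a, within_b = _hist(xa), _hist(xb)
    pooled = _hist(pooled_xy)
    if len(xa) and len(xb):
        from scipy.spatial.distance import cdist
        dx = cdist(xa, xb).ravel()
        cc, _ = np.histogram(dx[dx < edges[-1]], bins=edges)
        cross_counts = 2 * cc.astype(np.int64)
    else:
        cross_counts = np.zeros(len(edges) - 1, np.int64)
    cross = DistanceHistogram(edges, cross_counts, len(xa) + len(xb))
    return {"within_A": within_a, "within_B": within_b,
            "cross": cross, "pooled": pooled}


def write_histogram(hist: DistanceHistogram, path, *, sep=",") -> None:
    """Export as delimited text ``bin_lo,bin_hi,count``."""
    hist.to_frame().to_csv(path, sep=sep, index=False)
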