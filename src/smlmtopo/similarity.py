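"""Jaccard barcode similarity, heatmaps, and heterochromatin association.

Two bars are compared by the Jaccard index of their intervals —
intersection length over union length — giving 0 for disjoint bars and 1
for identical bars.  Two barcodes are compared per dimension by a
maximum-weight one-to-one matching of their bars on these interval
similarities; unmatched bars (when bar counts differ) contribute 0, so the
per-dimension similarity is the matching total divided by the larger bar
count.  The overall similarity averages the dimension-0 and dimension-1
values.  Before comparison, barcodes are scale-normalized (endpoints
divided by the barcode's scale reference, by default its largest finite
death) so that topological comparison is independent of object size.

Damage clusters are classified as heterochromatin-associated (HC) or not
(nHC) from the local heterochromatin-label point density in concentric
circular shells around the cluster center: HC when the mean density over
the inner shells reaches the threshold (default: the nucleus-wide mean
density of the heterochromatin channel).

Heatmaps order clusters HC block first, then nHC, so within- and
between-group topological homogeneity can be read off block-wise;
second-generation heatmaps average those block summaries per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .localizations import LocalizationTable
from .persistence import Bar, Barcode

logger = logging.getLogger(__name__)


def jaccard_interval(bar_a: Bar, bar_b: Bar) -> float:
    """Interval Jaccard index |a ∩ b| / |a ∪ b| of two bars.

    0 when the intervals are disjoint, 1 when identical; two identical
    degenerate (zero-length) bars also score 1.
    """
    if bar_a.dimension != bar_b.dimension:
        raise ValueError("bars must have the same dimension")
    if not (bar_a.finite and bar_b.finite):
        raise ValueError("interval Jaccard requires finite bars")
    inter = min(bar_a.death, bar_b.death) - max(bar_a.birth, bar_b.birth)
    union = max(bar_a.death, bar_b.death) - min(bar_a.birth, bar_b.birth)
    if union == 0.0:
        return 1.0  # identical degenerate bars
    return max(inter, 0.0) / union


def _normalized_intervals(bc: Barcode, dimension: int,
                          normalize: bool) -> np.ndarray:
    bars = [b for b in bc.dim(dimension) if b.finite]
    iv = np.array([[b.birth, b.death] for b in bars], float).reshape(-1, 2)
    if normalize and len(iv):
        ref = bc.scale_reference or bc.largest_finite_death
        if ref:
            iv = iv / ref
    return iv


def _interval_jaccard_matrix(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    inter = (np.minimum(ia[:, None, 1], ib[None, :, 1])
             - np.maximum(ia[:, None, 0], ib[None, :, 0]))
    union = (np.maximum(ia[:, None, 1], ib[None, :, 1])
             - np.minimum(ia[:, None, 0], ib[None, :, 0]))
    out = np.zeros(inter.shape)
    np.divide(np.maximum(inter, 0.0), union, out=out, where=union > 0)
    out[(union == 0)] = 1.0  # identical degenerate bars
    return out


def barcode_similarity(bc_a: Barcode, bc_b: Barcode, dimension: int,
                       *, normalize: bool = True,
                       matching: str = "assignment") -> float:
    """Jaccard similarity of two barcodes in one dimension, in [0, 1].

    ``matching="assignment"`` (default) solves the maximum-weight bipartite
    assignment on interval-Jaccard weights and divides the total by the
    larger bar count, so surplus bars penalize; ``matching="best"`` averages
    each bar's best-match score symmetrically instead.  Infinite bars are
    excluded (every barcode has the same single essential component).  Two
    empty barcodes count as identical (similarity 1, logged).
    """
    ia = _normalized_intervals(bc_a, dimension, normalize)
    ib = _normalized_intervals(bc_b, dimension, normalize)
    if len(ia) == 0 and len(ib) == 0:
        logger.info("both barcodes empty in dimension %d: similarity 1",
                    dimension)
        return 1.0
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    w = _interval_jaccard_matrix(ia, ib)
    if matching == "assignment":
        rows, cols = linear_sum_assignment(w, maximize=True)
        return float(w[rows, cols].sum() / max(len(ia), len(ib)))
    if matching == "best":
        return float(0.5 * (w.max(axis=1).mean() + w.max(axis=0).mean()))
    raise ValueError("matching must be 'assignment' or 'best'")


def overall_similarity(bc_a: Barcode, bc_b: Barcode, *, normalize: bool = True,
                       matching: str = "assignment") -> float:
    """Mean of the dimension-0 and dimension-1 barcode similarities."""
    return 0.5 * (barcode_similarity(bc_a, bc_b, 0, normalize=normalize,
                                     matching=matching)
                  + barcode_similarity(bc_a, bc_b, 1, normalize=normalize,
                                       matching=matching))


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """All-vs-all similarity matrix, HC block first then nHC.

    For the topology measures values lie in [0, 1] with a unit diagonal;
    for ``measure="size"`` the entry is the absolute size difference
    (small = similar) and is not bounded by 1.
    """

    values: np.ndarray
    labels: list          # (cluster_id, "HC"|"nHC") per row
    measure: str

    @property
    def hc_block_size(self) -> int:
        return sum(1 for _, flag in self.labels if flag == "HC")

    def block_summary(self) -> dict:
        """Mean HC–HC, nHC–nHC and HC–nHC values (off-diagonal only)."""
        k, n = self.hc_block_size, len(self.labels)
        v = self.values
        def _mean_off(a, b, same):
            if same:
                sub = v[np.ix_(a, a)]
                m = ~np.eye(len(a), dtype=bool)
                return float(sub[m].mean()) if len(a) > 1 else np.nan
            return float(v[np.ix_(a, b)].mean()) if len(a) and len(b) else np.nan
        hc, nhc = list(range(k)), list(range(k, n))
        return {"HC-HC": _mean_off(hc, hc, True),
                "nHC-nHC": _mean_off(nhc, nhc, True),
                "HC-nHC": _mean_off(hc, nhc, False)}

    def to_frame(self):
        import pandas as pd
        names = [f"{cid}:{flag}" for cid, flag in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)


def similarity_heatmap(barcodes, hc_labels, measure: str = "overall", *,
                       sizes=None, normalize: bool = True,
                       matching: str = "assignment") -> SimilarityMatrix:
    """All-vs-all similarity matrix over clusters, HC block first.

    ``measure``: ``dim0`` | ``dim1`` | ``overall`` (topology; unit diagonal)
    or ``size`` (absolute difference of the values in ``sizes``, e.g. RMS
    cluster sizes).  Rows are reordered so HC-labelled clusters come first.
    """
    barcodes = list(barcodes)
    hc_labels = list(hc_labels)
    if len(barcodes) != len(hc_labels):
        raise ValueError("one label per barcode required")
    if not barcodes:
        return SimilarityMatrix(np.zeros((0, 0)), [], measure)
    order = sorted(range(len(barcodes)),
                   key=lambda i: (hc_labels[i] != "HC", i))
    n = len(order)
    vals = np.zeros((n, n))
    if measure == "size":
        if sizes is None:
            raise ValueError("measure='size' needs the sizes argument")
        s = np.asarray([sizes[i] for i in order], float)
        vals = np.abs(s[:, None] - s[None, :])
    else:
        fn = {"dim0": lambda a, b: barcode_similarity(a, b, 0, normalize=normalize,
                                                      matching=matching),
              "dim1": lambda a, b: barcode_similarity(a, b, 1, normalize=normalize,
                                                      matching=matching),
              "overall": lambda a, b: overall_similarity(a, b, normalize=normalize,
                                                         matching=matching)}
        if measure not in fn:
            raise ValueError("measure must be size|dim0|dim1|overall")
        f = fn[measure]
        for i in range(n):
            vals[i, i] = f(barcodes[order[i]], barcodes[order[i]])
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = f(barcodes[order[i]],
                                            barcodes[order[j]])
    labels = [(order[i], hc_labels[order[i]] or "nHC") for i in range(n)]
    return SimilarityMatrix(vals, labels, measure)


def second_generation_heatmap(matrices) -> dict:
    """Average the block summaries of several first-generation heatmaps.

    ``matrices`` maps condition name -> list of :class:`SimilarityMatrix`
    (or is a bare list, treated as one unnamed condition).  Returns
    condition -> averaged ``{"HC-HC", "nHC-nHC", "HC-nHC"}``.
    """
    if isinstance(matrices, (list, tuple)):
        matrices = {"all": list(matrices)}
    out = {}
    for cond, mats in matrices.items():
        if not mats:
            raise ValueError(f"condition {cond!r} has no matrices")
        measures = {m.measure for m in mats}
        if len(measures) > 1:
            raise ValueError(f"condition {cond!r} mixes measures {measures}")
        summaries = [m.block_summary() for m in mats]
        out[cond] = {key: float(np.nanmean([s[key] for s in summaries]))
                     for key in ("HC-HC", "nHC-nHC", "HC-nHC")}
    return out


# ---------------------------------------------------------------------------
# Heterochromatin association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellSpec:
    """Concentric circular shells around a cluster center: ``n_shells``
    shells of ``shell_width`` nm; the innermost ``n_inner`` define the
    local-density region used for classification."""

    n_shells: int = 10
    shell_width: float = 50.0
    n_inner: int = 4

    def __post_init__(self):
        if self.n_shells < 1 or self.shell_width <= 0:
            raise ValueError("need n_shells >= 1 and positive shell_width")
        if not (1 <= self.n_inner <= self.n_shells):
            raise ValueError("n_inner must be in [1, n_shells]")

    @property
    def edges(self) -> np.ndarray:
        return self.shell_width * np.arange(self.n_shells + 1)


@dataclass
class ShellDensityProfile:
    """Heterochromatin point density (points per nm²) per concentric shell."""

    shell_edges: np.ndarray
    densities: np.ndarray

    def inner_mean(self, n_inner: int) -> float:
        """Point density over the union of the first ``n_inner`` shells."""
        areas = np.pi * np.diff(self.shell_edges ** 2)
        counts = self.densities * areas
        inner_area = areas[:n_inner].sum()
        return float(counts[:n_inner].sum() / inner_area)


def shell_density_profile(centroid, hc_points, shells: ShellSpec
                          ) -> ShellDensityProfile:
    """Density of heterochromatin-channel points in shells around a center."""
    xy = hc_points.xy if isinstance(hc_points, LocalizationTable) \
        else np.asarray(hc_points, float)
    edges = shells.edges
    if len(xy):
        r = np.hypot(xy[:, 0] - centroid[0], xy[:, 1] - centroid[1])
        counts, _ = np.histogram(r, bins=edges)
    else:
        counts = np.zeros(shells.n_shells)
    areas = np.pi * np.diff(edges ** 2)
    return ShellDensityProfile(edges, counts / areas)


def classify_hc_association(centroid, hc_points, shells: ShellSpec | None = None,
                            *, threshold: float | None = None,
                            field_area: float | None = None) -> str:
    """Classify one cluster center as ``"HC"`` or ``"nHC"``.

    HC when the mean heterochromatin density over the inner shells is at
    least ``threshold`` (points per nm²).  The default threshold is the
    nucleus-wide mean density of the heterochromatin channel, which needs
    ``field_area`` (nm²) or a table whose metadata carries a field spec.
    A heterochromatin channel with no points always classifies as nHC.
    """
    shells = shells or ShellSpec()
    n_hc = len(hc_points)
    if n_hc == 0:
        return "nHC"
    if threshold is None:
        if field_area is None and isinstance(hc_points, LocalizationTable):
            fld = hc_points.meta.get("field")
            field_area = getattr(fld, "area", None)
        if field_area is None:
            raise ValueError("default threshold needs field_area (nm²)")
        threshold = n_hc / field_area
    profile = shell_density_profile(centroid, hc_points, shells)
    return "HC" if profile.inner_mean(shells.n_inner) >= threshold else "nHC"


def classify_clusters(clusters, hc_points, shells: ShellSpec | None = None,
                      *, threshold: float | None = None,
                      field_area: float | None = None) -> list:
    """Label every cluster in place (``hc_label``) and return the labels."""
    labels = []
    for c in clusters:
        lab = classify_hc_association(c.centroid, hc_points, shells,
                                      threshold=threshold,
                                      field_area=field_area)
        c.hc_label = lab
        labels.append(lab)
    return labels


def write_similarity_matrix(matrix: SimilarityMatrix, path, *, sep=",") -> None:
    """Export as labeled delimited text (header row/column of ids+flags)."""
    matrix.to_frame().to_csv(path, sep=sep, index=True)
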