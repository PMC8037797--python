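"""Sphere-growth filtrations and persistence barcodes of point clouds.

The filtration grows a disc of radius α around every localization.  Two
points connect by an edge the moment their discs touch, i.e. at
α = d(i, j)/2; whenever the three edges of a triangle are present the
triangle is filled.  Up to dimension 2 this is the Vietoris–Rips complex at
scale 2α, and it is the default backend.  A 2D alpha-complex backend
(Delaunay triangulation with circumradius-based filtration values, the
construction typically used for whole-nucleus chromatin clouds) is available
via ``backend="alpha"``; its α parameter is the same sphere radius.

Persistence is computed over Z2: dimension-0 bars (connected components) by
union-find over the sorted edges — every merge kills one component born at
α = 0, and exactly one component per connected point set survives to
infinity; dimension-1 bars (holes) by standard boundary-matrix reduction of
the triangle columns over the cycle-creating edges.

Downstream barcode statistics follow the published whole-nucleus protocol:
bar endpoints are rounded to two decimals in µm and bars whose rounded birth
equals their rounded death are pruned; normalized per-nucleus histograms of
bar endpoints (death values) are averaged across nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .localizations import LocalizationTable


@dataclass(frozen=True)
class Bar:
    """One persistence bar: topological dimension (0 = component,
    1 = hole), birth α and death α in nm (death may be ``inf``)."""

    dimension: int
    birth: float
    death: float

    def __post_init__(self):
        if self.dimension not in (0, 1):
            raise ValueError("dimension must be 0 or 1")
        if self.death < self.birth:
            raise ValueError("death must be >= birth")

    @property
    def length(self) -> float:
        return self.death - self.birth

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.death))


@dataclass
class Barcode:
    """A set of persistence bars for one point set.

    ``scale_reference`` is the normalization divisor used by the similarity
    measures (by default the largest finite death); ``unit`` records the
    length unit of the endpoints ("nm" from the filtration, "um" after
    :func:`round_and_prune` with the default unit).
    """

    bars: list[Bar]
    n_points: int
    scale_reference: float | None = None
    unit: str = "nm"

    def dim(self, dimension: int) -> list[Bar]:
        return [b for b in self.bars if b.dimension == dimension]

    def finite_deaths(self, dimension: int) -> np.ndarray:
        return np.array([b.death for b in self.dim(dimension) if b.finite])

    @property
    def largest_finite_death(self) -> float:
        deaths = [b.death for b in self.bars if b.finite]
        return max(deaths) if deaths else 0.0


# ---------------------------------------------------------------------------
# Filtrations
# ---------------------------------------------------------------------------

@dataclass
class Filtration:
    """Simplicial filtration up to dimension 2.

    ``edges`` is an (E, 2) int array with ``edge_alphas`` (nm, the radius at
    which the two growth spheres touch); ``triangles`` an (T, 3) int array
    with ``triangle_alphas``.  Simplices are sorted by α.
    """

    n_points: int
    edges: np.ndarray
    edge_alphas: np.ndarray
    triangles: np.ndarray
    triangle_alphas: np.ndarray
    backend: str = "rips"
    points: np.ndarray | None = None


def _dedupe(xy: np.ndarray) -> np.ndarray:
    uniq, idx = np.unique(xy, axis=0, return_index=True)
    if len(uniq) < len(xy):
        warnings.warn(f"merged {len(xy) - len(uniq)} duplicate point(s) "
                      "before building the filtration", stacklevel=3)
        return xy[np.sort(idx)]
    return xy


def _as_xy(points) -> np.ndarray:
    if isinstance(points, LocalizationTable):
        return points.xy
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected (n, 2) coordinates or a LocalizationTable")
    return xy


def _enclosing_radius(dm: np.ndarray) -> float:
    """min over points of the max distance to any other point.  Beyond half
    this distance the complex is a cone, so all holes have died."""
    return float(dm.max(axis=0).min())


def _rips_filtration(xy: np.ndarray, max_alpha: float | None) -> Filtration:
    n = len(xy)
    if n == 1:
        z = np.zeros(0)
        return Filtration(1, np.zeros((0, 2), int), z,
                          np.zeros((0, 3), int), z, "rips", xy)
    dm = squareform(pdist(xy))
    if max_alpha is None:
        max_alpha = _enclosing_radius(dm) / 2.0
    iu, ju = np.triu_indices(n, k=1)
    keep = dm[iu, ju] / 2.0 <= max_alpha
    edges = np.column_stack([iu[keep], ju[keep]])
    e_alpha = dm[edges[:, 0], edges[:, 1]] / 2.0
    order = np.lexsort((edges[:, 1], edges[:, 0], e_alpha))
    edges, e_alpha = edges[order], e_alpha[order]
    # triangles: all i<j<k whose three edges are present
    adj = dm / 2.0 <= max_alpha
    np.fill_diagonal(adj, False)
    tris, t_alpha = [], []
    for a, b in edges:
        # common neighbors with index > b keep each triangle unique
        common = np.nonzero(adj[a] & adj[b])[0]
        for c in common[common > b]:
            tris.append((a, b, c))
            t_alpha.append(max(dm[a, b], dm[a, c], dm[b, c]) / 2.0)
    tris = np.array(tris, int).reshape(-1, 3)
    t_alpha = np.asarray(t_alpha, float)
    torder = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0], t_alpha)) \
        if len(tris) else np.zeros(0, int)
    return Filtration(n, edges, e_alpha, tris[torder], t_alpha[torder],
                      "rips", xy)


def _alpha_filtration(xy: np.ndarray) -> Filtration:
    """2D alpha-complex filtration (subcomplex of the Delaunay triangulation).

    Triangle value: circumradius.  Edge value: half-length when the edge's
    diametral disc is empty (Gabriel edge), else the smallest value of an
    incident triangle.
    """
    n = len(xy)
    if n < 3:
        return _rips_filtration(xy, None)
    try:
        tri = Delaunay(xy)
    except QhullError:
        return _rips_filtration(xy, None)  # degenerate (e.g. collinear) input

    def circumradius(p, q, r):
        a = np.linalg.norm(q - r)
        b = np.linalg.norm(p - r)
        c = np.linalg.norm(p - q)
        area2 = abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1]))
        if area2 == 0:
            return max(a, b, c) / 2.0
        return a * b * c / (2.0 * area2)

    simplices = np.sort(tri.simplices, axis=1)
    t_alpha = np.array([circumradius(xy[i], xy[j], xy[k])
                        for i, j, k in simplices])
    edge_tri: dict[tuple[int, int], list[float]] = {}
    for (i, j, k), ta in zip(simplices, t_alpha):
        for e in ((i, j), (i, k), (j, k)):
            edge_tri.setdefault(e, []).append(ta)
    edges, e_alpha = [], []
    for (i, j), tvals in edge_tri.items():
        half = np.linalg.norm(xy[i] - xy[j]) / 2.0
        mid = (xy[i] + xy[j]) / 2.0
        d = np.linalg.norm(xy - mid, axis=1)
        d[[i, j]] = np.inf
        gabriel = d.min() >= half
        edges.append((i, j))
        e_alpha.append(half if gabriel else min(tvals))
    edges = np.array(edges, int)
    e_alpha = np.array(e_alpha, float)
    order = np.lexsort((edges[:, 1], edges[:, 0], e_alpha))
    torder = np.lexsort((simplices[:, 2], simplices[:, 1], simplices[:, 0],
                         t_alpha))
    return Filtration(n, edges[order], e_alpha[order], simplices[torder],
                      t_alpha[torder], "alpha", xy)


def build_filtration(points, *, backend: str = "rips",
                     max_alpha: float | None = None) -> Filtration:
    """Build the sphere-growth filtration of a point set.

    Vertices enter at α = 0; an edge at α = d/2 (sphere contact); a triangle
    when its last edge is present (Rips) or at its alpha-complex value.
    Duplicate points are merged with a warning.  ``max_alpha`` (Rips only)
    truncates the filtration; the default — half the enclosing radius — is
    the smallest cutoff that provably retains every hole's death.
    """
    xy = _dedupe(_as_xy(points))
    if len(xy) == 0:
        raise ValueError("filtration needs at least one point")
    if backend == "rips":
        return _rips_filtration(xy, max_alpha)
    if backend == "alpha":
        return _alpha_filtration(xy)
    raise ValueError("backend must be 'rips' or 'alpha'")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

class _DSU:
    __slots__ = ("parent",)

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        """Union by index: the higher-index root dies.  Returns the dying
        root or None if already connected."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        self.parent[hi] = lo
        return hi


def persistence_barcode(filtration: Filtration) -> Barcode:
    """Dimension-0 and dimension-1 persistence bars of a filtration.

    Every vertex is born at α = 0; each merging edge kills one component
    (all births equal, so the higher-index representative dies — a
    deterministic tie-break of the elder rule).  Cycle-creating edges open
    holes that the reduced triangle columns close.  Holes still open at the
    truncation radius of a Rips filtration are reported with death = that
    radius (none exist at the default enclosing-radius cutoff).
    """
    n = filtration.n_points
    bars: list[Bar] = []
    dsu = _DSU(n)
    positive = np.zeros(len(filtration.edges), dtype=bool)
    for e, (i, j) in enumerate(filtration.edges):
        died = dsu.union(int(i), int(j))
        if died is None:
            positive[e] = True          # creates a cycle
        else:
            bars.append(Bar(0, 0.0, float(filtration.edge_alphas[e])))
    # one essential bar per surviving component
    n_comp = sum(1 for v in range(n) if dsu.find(v) == v)
    bars.extend(Bar(0, 0.0, np.inf) for _ in range(n_comp))

    # dimension 1: reduce triangle boundaries over Z2 (columns as bitsets)
    edge_index = {tuple(e): k for k, e in enumerate(map(tuple, filtration.edges))}
    pivot_owner: dict[int, int] = {}      # edge idx -> reduced column bitset
    killed: dict[int, float] = {}         # edge idx -> death alpha
    for t, (i, j, k) in enumerate(filtration.triangles):
        col = 0
        for e in ((int(i), int(j)), (int(i), int(k)), (int(j), int(k))):
            col ^= 1 << edge_index[e]
        while col:
            piv = col.bit_length() - 1
            if piv not in pivot_owner:
                pivot_owner[piv] = col
                killed[piv] = float(filtration.triangle_alphas[t])
                break
            col ^= pivot_owner[piv]
    max_alpha = float(filtration.edge_alphas.max()) if len(filtration.edge_alphas) else 0.0
    for e in np.nonzero(positive)[0]:
        birth = float(filtration.edge_alphas[e])
        death = killed.get(int(e))
        if death is None:
            death = np.inf if filtration.backend == "alpha" else max_alpha
        if death > birth or death == birth:
            bars.append(Bar(1, birth, min(death, np.inf)))
    bars = [b for b in bars if not (b.dimension == 1 and b.death <= b.birth)]
    bc = Barcode(sorted(bars, key=lambda b: (b.dimension, b.birth, b.death)),
                 n_points=n)
    bc.scale_reference = bc.largest_finite_death or None
    return bc


def barcode(points, *, backend: str = "rips",
            max_alpha: float | None = None,
            subsample: int | None = None, seed: int = 0) -> Barcode:
    """Convenience: filtration + persistence in one call.

    ``subsample`` draws that many points uniformly without replacement
    (seeded) before the filtration — useful for whole-nucleus clouds whose
    full Rips complex would be too large.
    """
    xy = _as_xy(points)
    if subsample is not None and subsample < len(xy):
        sel = np.random.default_rng(seed).choice(len(xy), subsample,
                                                 replace=False)
        xy = xy[np.sort(sel)]
    return persistence_barcode(build_filtration(xy, backend=backend,
                                                max_alpha=max_alpha))


def betti_numbers(filtration: Filtration, alpha: float) -> tuple[int, int]:
    """(B0, B1) at radius α: counts of bars with birth <= α < death."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    bc = persistence_barcode(filtration)
    b0 = sum(1 for b in bc.dim(0) if b.birth <= alpha < b.death)
    b1 = sum(1 for b in bc.dim(1) if b.birth <= alpha < b.death)
    return b0, b1


# ---------------------------------------------------------------------------
# Barcode post-processing
# ---------------------------------------------------------------------------

#: nm per unit for the rounding step; "um" (default) makes two-decimal
#: rounding a 20 nm granularity at the edge scale.
_UNIT_NM = {"nm": 1.0, "um": 1000.0}


def round_and_prune(bc: Barcode, decimals: int = 2, unit: str = "um") -> Barcode:
    """Round bar endpoints to ``decimals`` places in ``unit`` and drop bars
    whose rounded birth equals their rounded death.

    Infinite deaths are kept as infinite.  The returned barcode's endpoints
    are expressed in ``unit``.
    """
    if bc.unit not in _UNIT_NM:
        raise ValueError(f"unknown barcode unit {bc.unit!r}")
    factor = _UNIT_NM[bc.unit] / _UNIT_NM[unit]
    out = []
    for b in bc.bars:
        birth = round(b.birth * factor, decimals)
        death = b.death if not b.finite else round(b.death * factor, decimals)
        if birth == death:
            continue
        out.append(Bar(b.dimension, birth, death))
    ref = None
    if bc.scale_reference is not None:
        ref = bc.scale_reference * factor
    return Barcode(out, bc.n_points, ref, unit)


@dataclass
class EndpointHistogram:
    """Average normalized distribution of bar endpoints (deaths) per
    dimension across nuclei.  Each dimension's frequencies sum to 1."""

    bin_edges: np.ndarray
    freq_dim0: np.ndarray
    freq_dim1: np.ndarray
    n_nuclei: int
    skipped: dict = dc_field(default_factory=lambda: {0: 0, 1: 0})

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "freq_dim0": self.freq_dim0,
                             "freq_dim1": self.freq_dim1})


def endpoint_histogram(barcodes, bin_edges) -> EndpointHistogram:
    """Per-nucleus normalized histograms of bar death values, averaged
    (unweighted) across nuclei, per dimension.

    Infinite bars are excluded.  A nucleus with no finite bar in a dimension
    is skipped for that dimension (recorded in ``skipped``).
    """
    barcodes = list(barcodes)
    if not barcodes:
        raise ValueError("need at least one barcode")
    bin_edges = np.asarray(bin_edges, dtype=float)
    freqs = {0: [], 1: []}
    skipped = {0: 0, 1: 0}
    for bc in barcodes:
        for dim in (0, 1):
            deaths = bc.finite_deaths(dim)
            counts, _ = np.histogram(deaths, bins=bin_edges)
            total = counts.sum()
            if total == 0:
                skipped[dim] += 1
                continue
            freqs[dim].append(counts / total)
    def _avg(dim):
        if not freqs[dim]:
            return np.zeros(len(bin_edges) - 1)
        return np.mean(freqs[dim], axis=0)
    return EndpointHistogram(bin_edges, _avg(0), _avg(1), len(barcodes), skipped)


def write_barcode(bc: Barcode, path, *, sep=",") -> None:
    """Export as delimited text ``dimension,birth,death`` (death = 'inf'
    for essential bars)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit: {bc.unit}; n_points: {bc.n_points}\n")
        fh.write(sep.join(["dimension", "birth", "death"]) + "\n")
        for b in bc.bars:
            death = "inf" if not b.finite else repr(b.death)
            fh.write(f"{b.dimension}{sep}{b.birth!r}{sep}{death}\n")


def read_barcode(path, *, sep=",") -> Barcode:
    import pandas as pd
    unit = "nm"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#") and "unit:" in first:
            unit = first.split("unit:")[1].split(";")[0].strip()
    df = pd.read_csv(path, sep=sep, comment="#")
    bars = [Bar(int(r.dimension), float(r.birth), float(r.death))
            for r in df.itertuples()]
    bc = Barcode(bars, n_points=0, unit=unit)
    bc.scale_reference = bc.largest_finite_death or None
    return bc
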