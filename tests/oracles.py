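"""Independent brute-force oracles used by the test suite.

These are deliberately naive textbook implementations, kept separate from
the package's optimized code paths so the two can disagree.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Distances: O(N^2) ordered-pair histogram by explicit double loop
# ---------------------------------------------------------------------------

def brute_force_distance_histogram(xy, bin_edges):
    """Count ordered pairs (i, j), i != j, per half-open bin [lo, hi)."""
    xy = np.asarray(xy, float)
    counts = np.zeros(len(bin_edges) - 1, dtype=np.int64)
    for i in range(len(xy)):
        for j in range(len(xy)):
            if i == j:
                continue
            d = math.dist(xy[i], xy[j])
            for k in range(len(counts)):
                if bin_edges[k] <= d < bin_edges[k + 1]:
                    counts[k] += 1
                    break
    return counts


# ---------------------------------------------------------------------------
# Persistence: full boundary-matrix reduction over the complete filtration
# ---------------------------------------------------------------------------

def brute_force_rips_barcode(xy, drop_zero_length=True):
    """Textbook Z2 boundary-matrix reduction of the full (uncut) Rips
    filtration up to dimension 2, with alpha = half the edge length.

    Returns a sorted list of (dimension, birth, death) with death = inf for
    essential classes.  Zero-length dimension-1 bars are dropped by default
    (they carry no topological content).
    """
    xy = np.asarray(xy, float)
    n = len(xy)
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = math.dist(xy[i], xy[j])

    simplices = [((v,), 0.0) for v in range(n)]
    simplices += [((i, j), dist[(i, j)] / 2.0)
                  for (i, j) in itertools.combinations(range(n), 2)]
    for tri in itertools.combinations(range(n), 3):
        i, j, k = tri
        alpha = max(dist[(i, j)], dist[(i, k)], dist[(j, k)]) / 2.0
        simplices.append((tri, alpha))
    # faces must precede cofaces: sort by (alpha, dimension, vertices)
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s: k for k, (s, _) in enumerate(simplices)}

    columns = []
    for s, _ in simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append({index[f] for f in itertools.combinations(s, len(s) - 1)})

    low_of = {}
    pairs = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in low_of:
                low_of[low] = j
                pairs.append((low, j))
                break
            col ^= columns[low_of[low]]
    paired = {i for i, _ in pairs} | {j for _, j in pairs}

    bars = []
    for i, j in pairs:
        dim = len(simplices[i][0]) - 1
        if dim > 1:
            continue
        birth, death = simplices[i][1], simplices[j][1]
        if drop_zero_length and dim == 1 and death == birth:
            continue
        if dim == 0 and death == birth:
            continue  # cannot occur for distinct points
        bars.append((dim, birth, death))
    for k, (s, alpha) in enumerate(simplices):
        if k not in paired and len(s) <= 2:
            bars.append((len(s) - 1, alpha, math.inf))
    return sorted(bars)


# ---------------------------------------------------------------------------
# Geometry: rejection-sampling polygon centroid
# ---------------------------------------------------------------------------

def monte_carlo_centroid(vertices, n_samples=2_000_000, seed=0):
    """Area-weighted centroid of a convex polygon by rejection sampling."""
    from matplotlib.path import Path
    v = np.asarray(vertices, float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    inside = Path(v).contains_points(pts)
    return pts[inside].mean(axis=0)


# ---------------------------------------------------------------------------
# Clustering: brute-force density connectivity
# ---------------------------------------------------------------------------

def brute_force_density_clusters(xy, eps, min_pts):
    """Density-connected components by explicit graph search.

    Returns a list of frozensets of member indices (clusters containing at
    least one core point), border points attached to the cluster of their
    lowest-index core neighbor.
    """
    xy = np.asarray(xy, float)
    n = len(xy)
    neigh = [[j for j in range(n) if math.dist(xy[i], xy[j]) <= eps]
             for i in range(n)]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    label = [-1] * n
    current = 0
    for s in range(n):
        if not core[s] or label[s] != -1:
            continue
        stack, label[s] = [s], current
        while stack:
            u = stack.pop()
            for v in neigh[u]:
                if core[v] and label[v] == -1:
                    label[v] = current
                    stack.append(v)
        current += 1
    for i in range(n):
        if not core[i]:
            cnb = [j for j in neigh[i] if core[j]]
            if cnb:
                label[i] = label[min(cnb)]
    return [frozenset(i for i in range(n) if label[i] == c)
            for c in range(current)]
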