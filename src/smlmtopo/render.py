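"""Pointillist rendering of localization tables.

SMLM data are a coordinate list, not an image; a raster view is produced by
"splatting" events onto a canvas.  Three modes: ``dot`` (unit impulses),
``density`` (impulse intensity scaled by the k-nearest-neighbor local
density, so clustered events render brighter), and ``gaussian`` (each event
drawn as an isotropic Gaussian of width equal to its localization
precision).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .localizations import LocalizationTable
from .simulate import FieldSpec


def knn_density(xy: np.ndarray, k: int = 8) -> np.ndarray:
    """Local density estimate per point: k / (π r_k²) with r_k the distance
    to the k-th nearest neighbor."""
    n = len(xy)
    if n <= 1:
        return np.ones(n)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
    dist, _ = nn.kneighbors(xy)
    rk = dist[:, -1]
    rk[rk == 0] = np.min(rk[rk > 0]) if np.any(rk > 0) else 1.0
    return k / (np.pi * rk ** 2)


def render_pointillist(table: LocalizationTable, *, mode: str = "dot",
                       shape: tuple[int, int] = (512, 512),
                       field: FieldSpec | None = None,
                       knn_k: int = 8) -> np.ndarray:
    """Render one channel onto a float canvas of ``shape`` (rows, cols).

    Row 0 is the top of the image (y decreasing), column index tracks x.
    An empty table returns a zero canvas with a warning.
    """
    if mode not in ("dot", "density", "gaussian"):
        raise ValueError("mode must be dot|density|gaussian")
    h, w = shape
    canvas = np.zeros((h, w))
    if len(table) == 0:
        warnings.warn("empty localization table: blank canvas", stacklevel=2)
        return canvas
    fld = field or table.meta.get("field")
    xy = table.xy
    if fld is None:
        ox, oy = xy.min(axis=0)
        fw = max(np.ptp(xy[:, 0]), 1.0)
        fh = max(np.ptp(xy[:, 1]), 1.0)
    else:
        ox, oy = fld.origin
        fw, fh = fld.width, fld.height
    col = np.clip(((xy[:, 0] - ox) / fw * w).astype(int), 0, w - 1)
    row = np.clip((h - 1 - (xy[:, 1] - oy) / fh * h).astype(int), 0, h - 1)
    if mode == "dot":
        canvas[row, col] = 1.0
        return canvas
    if mode == "density":
        weights = knn_density(xy, knn_k)
        np.add.at(canvas, (row, col), weights)
        return canvas / canvas.max()
    # gaussian: splat each event on a local window, sigma = precision in px
    prec = table.data["precision_nm"].to_numpy(float)
    sx = np.maximum(prec / fw * w, 0.3)
    sy = np.maximum(prec / fh * h, 0.3)
    for r, c, sxi, syi in zip(row, col, sx, sy):
        half = int(np.ceil(3 * max(sxi, syi)))
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
        canvas[r0:r1, c0:c1] += np.exp(-0.5 * (((rr - r) / syi) ** 2
                                               + ((cc - c) / sxi) ** 2))
    return canvas / canvas.max()


def save_render(canvas: np.ndarray, path, *, cmap: str = "inferno") -> None:
    """Write a canvas to a PNG via matplotlib (no axes, exact pixels)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    plt.imsave(path, canvas, cmap=cmap)
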