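"""Interpolation of per-node displacement scores onto a pixelized disk.

The unit disk is discretized on a regular G x G grid over [-1, 1]^2 (pixel
centers, pixels whose center falls outside the disk are discarded).  Each
in-disk pixel j receives the weighted average of the scores of its k
hyperbolically nearest nodes (pre-surgery positions),

    C(j) = sum_i w_i * score_i / sum_i w_i,     w_i = 1 / d_hyp(j, i)^alpha,

an inverse-distance weighting whose exponent alpha controls smoothness:
small alpha gives near-uniform weights and a very smooth map, large alpha a
mosaic of nearest-node tiles.  Defaults: G = 80, k = 20, alpha = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import hyperbolic_distance, wrap_angle
from .embedding import DiskEmbedding


@dataclass(frozen=True)
class RasterParams:
    grid_size: int = 80
    k: int = 20
    alpha: float = 0.1

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class DiskRaster:
    """Interpolated values on the in-disk pixels of a G x G grid."""

    grid_size: int
    centers_x: np.ndarray  # (G,) pixel-center coordinates per axis
    in_disk: np.ndarray  # (G, G) boolean mask, row-major [iy, ix]
    values: np.ndarray  # (n_in_disk,) values for in-disk pixels in scan order

    def dense(self, fill=np.nan) -> np.ndarray:
        out = np.full((self.grid_size, self.grid_size), fill, dtype=float)
        out[self.in_disk] = self.values
        return out

    def to_frame(self) -> pd.DataFrame:
        g = self.grid_size
        iy, ix = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        dense = self.dense()
        return pd.DataFrame(
            {
                "pixel_row": iy.ravel(),
                "pixel_col": ix.ravel(),
                "x": np.broadcast_to(self.centers_x[None, :], (g, g)).ravel(),
                "y": np.broadcast_to(self.centers_x[:, None], (g, g)).ravel(),
                "in_disk": self.in_disk.ravel().astype(int),
                "value": dense.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pixel_grid(grid_size: int):
    """Pixel centers and the in-disk mask of the G x G grid over [-1, 1]^2.

    Centers sit at ``(u + 0.5) / G * 2 - 1`` for u = 0..G-1 per axis; the
    mask is True where the center radius is <= 1.  Returns
    ``(centers_1d, in_disk_mask)`` with the mask indexed ``[iy, ix]``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    centers = (np.arange(grid_size) + 0.5) / grid_size * 2.0 - 1.0
    xx, yy = np.meshgrid(centers, centers, indexing="xy")
    mask = np.sqrt(xx**2 + yy**2) <= 1.0
    return centers, mask


def _pixel_polar(grid_size: int):
    centers, mask = pixel_grid(grid_size)
    xx, yy = np.meshgrid(centers, centers, indexing="xy")
    px, py = xx[mask], yy[mask]
    return centers, mask, np.hypot(px, py), wrap_angle(np.arctan2(py, px))


def interpolate(
    emb_pre: DiskEmbedding,
    scores: np.ndarray,
    params: RasterParams | None = None,
) -> DiskRaster:
    """Interpolate node scores to the disk grid (inverse-distance k-NN).

    Distances from each pixel center (treated as a disk point via its polar
    form) to the nodes' pre-surgery positions are hyperbolic.  Ties at the
    k-th rank are broken by ascending node index (node-id order), and a
    pixel coinciding exactly with a node takes that node's score (the limit
    of the weighting as d -> 0).
    """
    params = params or RasterParams()
    scores = np.asarray(scores, dtype=float)
    n = emb_pre.n_nodes
    if scores.shape != (n,):
        raise ValueError("need exactly one score per node")
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds node count {n}")
    centers, mask, pr, ptheta = _pixel_polar(params.grid_size)
    # (n_pixels, n_nodes) hyperbolic distance matrix
    d = hyperbolic_distance(
        pr[:, None], ptheta[:, None], emb_pre.radius[None, :], emb_pre.theta[None, :]
    )
    # k nearest per pixel; stable argsort keeps ascending node order on ties
    nn = np.argsort(d, axis=1, kind="stable")[:, : params.k]
    dn = np.take_along_axis(d, nn, axis=1)
    sn = scores[nn]
    values = np.empty(d.shape[0], dtype=float)
    # a pixel on a node dominates only for alpha > 0; at alpha = 0 all
    # weights are 1 and the plain k-NN mean applies even at d = 0
    exact = (dn[:, 0] == 0.0) if params.alpha > 0 else np.zeros(d.shape[0], bool)
    if exact.any():
        values[exact] = sn[exact, 0]
    rest = ~exact
    w = dn[rest] ** (-params.alpha)
    values[rest] = (w * sn[rest]).sum(axis=1) / w.sum(axis=1)
    return DiskRaster(params.grid_size, centers, mask, values)


def raster_stack(rasters) -> np.ndarray:
    """Stack the in-disk values of same-grid rasters into (n_subjects, n_pixels)."""
    rasters = list(rasters)
    g = rasters[0].grid_size
    for r in rasters:
        if r.grid_size != g or not np.array_equal(r.in_disk, rasters[0].in_disk):
            raise ValueError("rasters must share an identical grid")
    return np.vstack([r.values for r in rasters])
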