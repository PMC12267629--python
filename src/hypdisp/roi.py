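"""Group-level pixelwise comparison of displacement maps and ROI extraction.

Interpolated displacement maps of the two outcome groups are compared pixel
by pixel with a two-sided, equal-variance Student's t test; pixels with
p <= p_threshold form the region of interest (ROI), labeled into connected
components under 4- or 8-connectivity.  Nodes whose pre-surgery position
falls inside the ROI for at least ``node_in_roi_fraction`` of the patients
are the discriminant nodes; a companion report lists the nodes that lost at
least ``resected_display_fraction`` of their connections at surgery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .embedding import DiskEmbedding
from .io import Connectome
from .raster import DiskRaster, raster_stack


@dataclass(frozen=True)
class RoiParams:
    p_threshold: float = 0.05
    connectivity: int = 8  # pixel adjacency rule, 4 or 8
    node_in_roi_fraction: float = 0.80
    resected_display_fraction: float = 0.40
    equal_var: bool = True  # classical Student's t (not Welch)

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for name in ("node_in_roi_fraction", "resected_display_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class RoiMask:
    """Significance mask over the in-disk pixels, with test statistics."""

    grid_size: int
    in_disk: np.ndarray  # (G, G) boolean
    significant: np.ndarray  # (n_in_disk,) boolean, scan order of in-disk pixels
    t_stat: np.ndarray
    p_value: np.ndarray
    components: np.ndarray  # (n_in_disk,) int labels, 0 = not significant
    zero_variance: np.ndarray  # pixels where the pooled variance vanished

    @property
    def n_components(self) -> int:
        return int(self.components.max()) if self.components.size else 0

    @property
    def n_pixels(self) -> int:
        return int(self.significant.sum())

    def dense_mask(self) -> np.ndarray:
        out = np.zeros((self.grid_size, self.grid_size), dtype=bool)
        out[self.in_disk] = self.significant
        return out

    def to_frame(self) -> pd.DataFrame:
        iy, ix = np.nonzero(self.in_disk)
        return pd.DataFrame(
            {
                "pixel_row": iy,
                "pixel_col": ix,
                "significant": self.significant.astype(int),
                "component": self.components,
                "t": self.t_stat,
                "p": self.p_value,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _label_components(dense_mask: np.ndarray, connectivity: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, _ = ndimage.label(dense_mask, structure=structure)
    return labels


def pixelwise_ttest(group_a, group_b, params: RoiParams | None = None) -> RoiMask:
    """Two-sample Student's t test at every in-disk pixel.

    ``group_a`` and ``group_b`` are lists of same-grid :class:`DiskRaster`;
    the returned mask marks pixels with p <= p_threshold.  Pixels with zero
    pooled variance are flagged and treated as non-significant (p = 1).
    No multiple-comparison correction is applied across pixels; the
    leave-one-out prediction wrapper provides out-of-sample control.
    """
    params = params or RoiParams()
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 rasters per group")
    a = raster_stack(group_a)
    b = raster_stack(group_b)
    if a.shape[1] != b.shape[1] or not np.array_equal(
        group_a[0].in_disk, group_b[0].in_disk
    ):
        raise ValueError("groups must share an identical grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=params.equal_var)
    zero_var = ~np.isfinite(t)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    sig = p <= params.p_threshold
    ref = group_a[0]
    dense = np.zeros((ref.grid_size, ref.grid_size), dtype=bool)
    dense[ref.in_disk] = sig
    labels = _label_components(dense, params.connectivity)
    return RoiMask(
        grid_size=ref.grid_size,
        in_disk=ref.in_disk,
        significant=sig,
        t_stat=t,
        p_value=p,
        components=labels[ref.in_disk],
        zero_variance=zero_var,
    )


def roi_median_feature(raster: DiskRaster, roi: RoiMask) -> float:
    """Median interpolated value over all ROI pixels (components pooled).

    Returns ``nan`` when the ROI is empty; the prediction module treats
    that as a missing feature.
    """
    if not np.array_equal(raster.in_disk, roi.in_disk):
        raise ValueError("raster and ROI must share an identical grid")
    if roi.n_pixels == 0:
        return float("nan")
    return float(np.median(raster.values[roi.significant]))


def _node_pixel_indices(emb: DiskEmbedding, grid_size: int):
    """Map each node's disk position to its containing pixel (iy, ix)."""
    x = emb.radius * np.cos(emb.theta)
    y = emb.radius * np.sin(emb.theta)
    ix = np.clip(((x + 1.0) / 2.0 * grid_size).astype(int), 0, grid_size - 1)
    iy = np.clip(((y + 1.0) / 2.0 * grid_size).astype(int), 0, grid_size - 1)
    return iy, ix


def discriminant_nodes(
    cohort_embeddings,
    roi: RoiMask,
    params: RoiParams | None = None,
    hemisphere=None,
) -> pd.DataFrame:
    """Nodes inside the ROI for >= node_in_roi_fraction of the patients.

    ``cohort_embeddings`` are the patients' aligned pre-surgery embeddings.
    A node is "in ROI" for a patient when its position's containing pixel is
    significant.  Returns a frame (node_id, hemisphere-less) with the
    per-node fraction and the selected flag, for all nodes with fraction > 0.
    """
    params = params or RoiParams()
    embs = list(cohort_embeddings)
    if not embs:
        raise ValueError("need at least one embedding")
    dense = roi.dense_mask()
    counts = np.zeros(embs[0].n_nodes, dtype=int)
    for emb in embs:
        iy, ix = _node_pixel_indices(emb, roi.grid_size)
        counts += dense[iy, ix].astype(int)
    frac = counts / len(embs)
    df = pd.DataFrame(
        {
            "node_id": embs[0].node_ids,
            "fraction_in_roi": frac,
            "discriminant": frac >= params.node_in_roi_fraction,
        }
    )
    if hemisphere is not None:
        df.insert(1, "hemisphere", list(hemisphere))
    return df


def resected_node_report(
    pre: Connectome, post: Connectome, params: RoiParams | None = None
) -> pd.DataFrame:
    """Nodes that lost >= resected_display_fraction of their connections.

    Frame columns: node_id, hemisphere, degree_pre, degree_post,
    fraction_removed, displayed.  Pre-degree-0 nodes are excluded from the
    display set and flagged with fraction_removed = nan.
    """
    params = params or RoiParams()
    if pre.node_ids != post.node_ids:
        raise ValueError("pre and post networks must share node order")
    d_pre = pre.degrees.astype(float)
    d_post = post.degrees.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        removed = np.where(d_pre > 0, (d_pre - d_post) / d_pre, np.nan)
    displayed = np.where(
        np.isnan(removed), False, removed >= params.resected_display_fraction
    )
    return pd.DataFrame(
        {
            "node_id": pre.node_ids,
            "hemisphere": pre.hemisphere,
            "degree_pre": d_pre.astype(int),
            "degree_post": d_post.astype(int),
            "fraction_removed": removed,
            "displayed": displayed.astype(bool),
        }
    )
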