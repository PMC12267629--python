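"""Coalescent embedding of a binary connectome into the hyperbolic disk.

Pipeline: repulsion-attraction (RA) edge weighting -> weighted geodesic
matrix -> classical multidimensional scaling to 2-D (the Isomap projection)
-> equidistant re-spacing of the angular coordinates -> radii from the
descending-degree rank, rescaled into the unit disk.

The RA weight of an edge (i, j) is

    omega_ij = (d_i + d_j + d_i * d_j) / (1 + CN_ij),

with d the binary degrees and CN the number of common neighbors.  Edges
embedded in well-connected neighborhoods (many common neighbors) get small
weights; since omega is used as an edge *length* in the geodesic
computation, topologically important edges become short and the projection
keeps their endpoints close.

The radius of the node of degree-rank i (1 = highest degree) is

    r_i = (2 / zeta) * (beta * ln i + (1 - beta) * ln N),

then all radii are divided by r_N so the disk has unit radius.  High-degree
hubs therefore sit near the center (rescaled radius (1 - beta) for the
rank-1 node when zeta = 1) and leaves on the rim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .geometry import TWO_PI, apply_transform, find_rotation, wrap_angle
from .io import Connectome, ValidationError


@dataclass(frozen=True)
class EmbeddingParams:
    """Curvature (zeta > 0) and fading (0 < beta <= 1) parameters."""

    zeta: float = 1.0
    beta: float = 0.9

    def __post_init__(self):
        if not self.zeta > 0:
            raise ValueError("zeta must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


@dataclass(frozen=True)
class DiskEmbedding:
    """Polar coordinates of every node on the unit hyperbolic disk.

    ``radius`` is the rescaled radial coordinate in [1 - beta, 1] (for
    zeta = 1), ``theta`` the equidistant angle in [0, 2*pi), ``rank`` the
    1-based descending-degree rank and ``isolated`` flags degree-0 nodes
    whose angle was not derived from the geodesic projection.
    """

    node_ids: tuple
    radius: np.ndarray
    theta: np.ndarray
    degree: np.ndarray
    rank: np.ndarray
    isolated: np.ndarray
    params: EmbeddingParams

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def rotated(self, radius=None, theta=None) -> "DiskEmbedding":
        """Copy with replaced coordinates (used by alignment)."""
        return DiskEmbedding(
            self.node_ids,
            self.radius if radius is None else np.asarray(radius, dtype=float),
            self.theta if theta is None else np.asarray(theta, dtype=float),
            self.degree,
            self.rank,
            self.isolated,
            self.params,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "r": self.radius,
                "theta": self.theta,
                "degree": self.degree,
                "rank": self.rank,
                "flag_isolated": self.isolated.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ra_weight(net: Connectome) -> np.ndarray:
    """Repulsion-attraction edge weights as a dense symmetric matrix.

    Entries are 0 where no edge exists; every existing edge gets
    ``(d_i + d_j + d_i d_j) / (1 + CN_ij) > 0``.
    """
    adj = net.adjacency.astype(float)
    if adj.sum() == 0:
        raise ValidationError("cannot RA-weight an edgeless graph")
    deg = adj.sum(axis=1)
    cn = adj @ adj  # common-neighbor counts
    num = deg[:, None] + deg[None, :] + deg[:, None] * deg[None, :]
    w = num / (1.0 + cn)
    return w * adj


def geodesic_matrix(weights: np.ndarray, bridge_factor: float = 1.05) -> np.ndarray:
    """All-pairs shortest-path lengths using the RA weights as edge lengths.

    If the weighted graph is disconnected, cross-component entries are set
    to ``bridge_factor`` times the largest finite geodesic, which keeps the
    subsequent MDS finite with minimal rank distortion.
    """
    g = csr_matrix(weights)
    d = shortest_path(g, method="D", directed=False)
    finite = np.isfinite(d)
    if not finite.all():
        dmax = d[finite].max() if finite.any() else 1.0
        d[~finite] = bridge_factor * dmax
    return d


def classical_mds_2d(dist: np.ndarray, node_ids=None) -> np.ndarray:
    """Classical MDS: double-center -1/2 * D^2 and keep the top-2 eigenpairs.

    Eigenvector signs are fixed deterministically: the node with the
    lexicographically smallest id gets x >= 0, and the next-smallest id with
    a nonzero y gets y >= 0, so repeated runs are bit-identical.
    """
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    lam = np.maximum(vals[order], 0.0)
    xy = vecs[:, order] * np.sqrt(lam)[None, :]
    if node_ids is None:
        anchor_order = np.arange(n)
    else:
        anchor_order = np.argsort(np.asarray(node_ids, dtype=object))
    for axis in range(2):
        for idx in anchor_order:
            v = xy[idx, axis]
            if abs(v) > 1e-12:
                if v < 0:
                    xy[:, axis] = -xy[:, axis]
                break
    return xy


def project_2d(weights: np.ndarray, node_ids=None, require_connected: bool = True):
    """Project an RA-weighted graph to the plane via geodesics + classical MDS.

    With ``require_connected`` the caller is told which components exist
    instead of silently bridging them; the embedding of post-surgery graphs
    passes ``require_connected=False`` and relies on the finite bridging of
    :func:`geodesic_matrix`.
    """
    g = csr_matrix(weights)
    n_comp, labels = connected_components(g, directed=False)
    if require_connected and n_comp > 1:
        sizes = np.bincount(labels)
        raise ValidationError(
            f"graph is disconnected: {n_comp} components with sizes {sizes.tolist()}"
        )
    d = geodesic_matrix(weights)
    return classical_mds_2d(d, node_ids=node_ids)


def equidistant_angles(xy: np.ndarray, node_ids=None, n_slots: int | None = None):
    """Replace raw atan2 angles by uniformly spaced ones, preserving order.

    Nodes are sorted by raw angle (ties broken by ascending node id) and the
    node at sorted position q receives ``theta = 2*pi*q / n_slots``.
    """
    n = xy.shape[0]
    if n_slots is None:
        n_slots = n
    raw = wrap_angle(np.arctan2(xy[:, 1], xy[:, 0]))
    if node_ids is None:
        keys = np.arange(n)
    else:
        keys = np.asarray(node_ids, dtype=object)
    order = np.lexsort((keys, raw))
    theta = np.empty(n, dtype=float)
    theta[order] = TWO_PI * np.arange(n) / n_slots
    return theta


def degree_ranks(degrees: np.ndarray, node_ids) -> np.ndarray:
    """1-based descending-degree ranks; ties broken by ascending node id."""
    keys = np.asarray(node_ids, dtype=object)
    order = np.lexsort((keys, -np.asarray(degrees)))
    rank = np.empty(len(keys), dtype=int)
    rank[order] = np.arange(1, len(keys) + 1)
    return rank


def radial_coordinates(net: Connectome, params: EmbeddingParams | None = None):
    """Native and rescaled radii from the descending-degree rank.

    Returns ``(native, rescaled, rank)`` where
    ``native_i = (2/zeta)(beta ln i + (1-beta) ln N)`` and rescaled radii
    are divided by the rank-N value so the disk has unit radius.
    """
    params = params or EmbeddingParams()
    n = net.n_nodes
    rank = degree_ranks(net.degrees, net.node_ids)
    native = (2.0 / params.zeta) * (
        params.beta * np.log(rank) + (1.0 - params.beta) * np.log(n)
    )
    r_outer = (2.0 / params.zeta) * np.log(n)  # rank-N native radius
    rescaled = native / r_outer
    return native, rescaled, rank


def embed(
    net: Connectome,
    params: EmbeddingParams | None = None,
    theta_fallback: np.ndarray | None = None,
    allow_disconnected: bool = False,
) -> DiskEmbedding:
    """Full coalescent embedding of a connectome.

    Degree-0 nodes (possible after a resection) carry no geodesic
    information: they are excluded from the projection, flagged in the
    output, and placed at the angle given per node by ``theta_fallback``
    (typically the subject's pre-surgery embedding) or at 0.  The remaining
    nodes are re-spaced uniformly among themselves.
    """
    params = params or EmbeddingParams()
    n = net.n_nodes
    deg = net.degrees
    isolated = deg == 0
    theta = np.zeros(n, dtype=float)
    active = ~isolated
    if active.sum() < 2:
        raise ValidationError("need at least 2 connected nodes to embed")
    sub = net.adjacency[np.ix_(active, active)]
    sub_net = Connectome(
        tuple(np.asarray(net.node_ids, dtype=object)[active]),
        tuple(np.asarray(net.hemisphere, dtype=object)[active]),
        sub,
    )
    w = ra_weight(sub_net)
    xy = project_2d(
        w,
        node_ids=sub_net.node_ids,
        require_connected=not (allow_disconnected or isolated.any()),
    )
    theta[active] = equidistant_angles(xy, node_ids=sub_net.node_ids)
    if isolated.any():
        if theta_fallback is not None:
            theta[isolated] = wrap_angle(np.asarray(theta_fallback, dtype=float))[
                isolated
            ]
        else:
            theta[isolated] = 0.0
    _, rescaled, rank = radial_coordinates(net, params)
    return DiskEmbedding(
        node_ids=net.node_ids,
        radius=rescaled,
        theta=theta,
        degree=deg,
        rank=rank,
        isolated=isolated,
        params=params,
    )


def align_to_reference(emb: DiskEmbedding, ref: DiskEmbedding):
    """Rotate (and possibly reflect) an embedding onto a reference.

    Returns ``(aligned_embedding, alignment)`` where the alignment records
    the applied rotation, whether a reflection was used, and the achieved
    summed-displacement loss.  Radii are never altered.
    """
    if emb.node_ids != ref.node_ids:
        raise ValidationError("embedding and reference must share node ids")
    result = find_rotation(ref.radius, ref.theta, emb.radius, emb.theta)
    aligned = emb.rotated(theta=apply_transform(emb.theta, result))
    return aligned, result
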