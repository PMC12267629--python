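"""Synthetic cohorts of two-hemisphere connectomes with simulated resections.

The base graphs are hyperbolic random geometric graphs built on a shared
cohort-level "atlas": one set of true coordinates per cohort (radii
quasi-uniform in hyperbolic area up to a disk radius R, angles uniform in
[0, pi) for the left hemisphere and [pi, 2*pi) for the right), perturbed
per subject by a small coordinate jitter — mirroring real cohorts, where
every subject carries the same anatomical regions with similar but not
identical connectivity.  Each node pair is then connected independently
per subject with the Fermi probability

    p(i, j) = 1 / (1 + exp((d_hyp(i, j) - R) / (2 T))),

so short hyperbolic distances mean near-certain edges and the temperature T
controls clustering.  R is calibrated once per configuration so the
expected mean degree matches ``avg_degree``.  Such graphs are degree-
heterogeneous, clustered, and carry ground-truth coordinates against which
the embedding stage can be validated.

A "surgery" deletes a fraction of the incident edges of a compact angular
sector of one hemisphere (the resection).  A patient-group effect is
planted contralaterally: for poor-outcome patients a fraction delta of the
edges incident to the mirror sector of the opposite hemisphere is rewired
by degree-preserving swaps *before* the resection, so the pre/post pair
inherits the perturbation and group differences appear in the displacement
maps away from the resection site.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import TWO_PI, hyperbolic_distance, wrap_angle, angular_separation
from .io import (
    CohortRecord,
    CohortTable,
    Connectome,
    ValidationError,
    write_cohort,
    write_connectome,
    write_node_table,
)


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration cannot be realized."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one synthetic cohort.

    Defaults mirror the study design the pipeline targets: a 114-node
    two-hemisphere atlas, 16 favorable / 8 poor patients plus healthy
    controls, a compact 10-node "temporal lobe" sector losing 90% of its
    connections at surgery, and a contralateral rewiring effect of
    strength ``effect_size`` planted in the poor-outcome group.
    """

    n_nodes: int = 114
    n_favorable: int = 16
    n_poor: int = 8
    n_controls: int = 5
    avg_degree: float = 12.0
    temperature: float = 0.1
    resection_size: int = 10
    resection_fraction: float = 0.9
    effect_size: float = 0.6
    side_mix: float = 0.5
    angle_jitter: float = 0.05  # SD of per-subject angular noise, radians
    radius_jitter: float = 0.05  # SD of per-subject radial noise, fraction of R
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 4 or self.n_nodes % 2:
            raise ConfigurationError("n_nodes must be even and >= 4")
        for name in ("resection_fraction", "effect_size", "side_mix"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be >= 0")
        if self.angle_jitter < 0 or self.radius_jitter < 0:
            raise ConfigurationError("jitter amplitudes must be >= 0")
        if min(self.n_favorable, self.n_poor, self.n_controls) < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if not 0 < self.avg_degree <= self.n_nodes - 1:
            raise ConfigurationError("avg_degree must lie in (0, n_nodes - 1]")
        if not 0 < self.resection_size <= self.n_nodes // 2:
            raise ConfigurationError("resection_size must fit in one hemisphere")


@dataclass(frozen=True)
class GroundTruth:
    """Generative coordinates and planted node sets for one subject."""

    true_radius: np.ndarray
    true_angle: np.ndarray
    resected_nodes: tuple  # node indices, all in the operated hemisphere
    contralateral_sector: tuple  # mirror sector in the opposite hemisphere
    side: str
    subject_seed: int


def _node_labels(n: int) -> tuple:
    width = len(str(n - 1))
    return tuple(f"n{idx:0{width}d}" for idx in range(n))


def _hemispheres(n: int) -> tuple:
    half = n // 2
    return tuple(["left"] * half + ["right"] * (n - half))


def atlas_coordinates(config: SyntheticConfig, R: float):
    """Cohort-level true coordinates, deterministic from ``config.seed``.

    All subjects of a cohort share these (up to per-subject jitter), the
    way real subjects share one parcellation with similar connectivity.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0xA71A5]).generate_state(1)
    )
    n = config.n_nodes
    half = n // 2
    u = rng.random(n)
    radius = np.arccosh(1.0 + u * (np.cosh(R) - 1.0))  # uniform in hyperbolic area
    angle = np.empty(n)
    angle[:half] = rng.random(half) * np.pi
    angle[half:] = np.pi + rng.random(n - half) * np.pi
    return radius, angle


def _sample_coordinates(config: SyntheticConfig, rng: np.random.Generator, R: float):
    """Per-subject coordinates: shared atlas plus small jitter."""
    base_r, base_a = atlas_coordinates(config, R)
    radius = base_r + rng.normal(0.0, config.radius_jitter * R, base_r.size)
    radius = np.clip(radius, 1e-3, R)
    angle = wrap_angle(base_a + rng.normal(0.0, config.angle_jitter, base_a.size))
    return radius, angle


def _edge_probability(d: np.ndarray, R: float, T: float) -> np.ndarray:
    if T <= 0:
        return (d < R).astype(float)
    # clipped logistic argument to avoid overflow
    z = np.clip((d - R) / (2.0 * T), -700, 700)
    return 1.0 / (1.0 + np.exp(z))


def calibrate_disk_radius(config: SyntheticConfig) -> float:
    """Bisection on R so the expected mean degree matches ``avg_degree``.

    Calibration evaluates the expected degree on the cohort's atlas
    coordinates, making R a deterministic function of the configuration;
    individual subjects then vary around the target degree.
    """
    n = config.n_nodes
    ii, jj = np.triu_indices(n, k=1)

    def mean_degree(R):
        rad, ang = atlas_coordinates(config, R)
        d = hyperbolic_distance(rad[ii], ang[ii], rad[jj], ang[jj])
        p = _edge_probability(d, R, config.temperature)
        return 2.0 * p.sum() / n

    # expected degree decreases with R (larger disk = sparser graph)
    lo, hi = 1e-3, 2.0 * np.log(n) + 10.0
    if mean_degree(lo) < config.avg_degree:
        raise ConfigurationError(
            f"avg_degree={config.avg_degree} unreachable for n_nodes={n}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_degree(mid) > config.avg_degree:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _repair_connectivity(
    adj: np.ndarray, radius: np.ndarray, angle: np.ndarray
) -> np.ndarray:
    """Bridge minor components to the giant one with minimal edits.

    Each minor component's highest-degree node is connected to the
    hyperbolically nearest node of the giant component.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = adj.copy()
    while True:
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        if n_comp == 1:
            return adj
        sizes = np.bincount(labels)
        giant = int(np.argmax(sizes))
        minor = int(np.argmin(np.where(np.arange(n_comp) == giant, np.inf, sizes)))
        members = np.flatnonzero(labels == minor)
        deg = adj.sum(axis=1)
        v = members[np.argmax(deg[members])]
        targets = np.flatnonzero(labels == giant)
        d = hyperbolic_distance(radius[v], angle[v], radius[targets], angle[targets])
        w = targets[np.argmin(d)]
        adj[v, w] = adj[w, v] = 1


def _sector_indices(
    angle: np.ndarray, hemisphere: tuple, side: str, size: int
) -> np.ndarray:
    """The ``size`` nodes of one hemisphere closest in angle to its sector
    center (pi/2 for left, 3*pi/2 for right): a compact angular sector."""
    center = np.pi / 2 if side == "left" else 3 * np.pi / 2
    hemi = np.asarray(hemisphere, dtype=object) == side
    idx = np.flatnonzero(hemi)
    gaps = angular_separation(angle[idx], center)
    return idx[np.argsort(gaps, kind="stable")[:size]]


def generate_base_connectome(
    config: SyntheticConfig,
    subject_seed: int,
    side: str = "left",
    disk_radius: float | None = None,
):
    """One hyperbolic random geometric graph plus its ground truth.

    ``side`` fixes which hemisphere the resection sector occupies; the
    contralateral sector is its angular mirror in the other hemisphere.
    """
    R = disk_radius if disk_radius is not None else calibrate_disk_radius(config)
    rng = np.random.default_rng(int(subject_seed))
    radius, angle = _sample_coordinates(config, rng, R)
    n = config.n_nodes
    ii, jj = np.triu_indices(n, k=1)
    d = hyperbolic_distance(radius[ii], angle[ii], radius[jj], angle[jj])
    p = _edge_probability(d, R, config.temperature)
    edges = rng.random(p.size) < p
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[edges], jj[edges]] = 1
    adj += adj.T
    adj = _repair_connectivity(adj, radius, angle)
    hemisphere = _hemispheres(n)
    net = Connectome(_node_labels(n), hemisphere, adj)
    # sectors from the shared atlas angles: the same anatomical nodes are
    # resected in every same-side subject, as in a standardized resection
    _, atlas_angle = atlas_coordinates(config, R)
    resected = _sector_indices(atlas_angle, hemisphere, side, config.resection_size)
    other = "right" if side == "left" else "left"
    contral = _sector_indices(atlas_angle, hemisphere, other, config.resection_size)
    truth = GroundTruth(
        true_radius=radius,
        true_angle=angle,
        resected_nodes=tuple(int(v) for v in resected),
        contralateral_sector=tuple(int(v) for v in contral),
        side=side,
        subject_seed=int(subject_seed),
    )
    return net, truth


def apply_resection(
    net: Connectome, truth: GroundTruth, fraction: float, seed: int
) -> Connectome:
    """Delete ``round(fraction * m_v)`` incident edges of every resected node.

    ``m_v`` is the node's pre-surgery degree.  Edges internal to the
    resected set count for both endpoints; nodes are processed in index
    order and each removes only as many further edges as needed to reach
    its quota.  No edges are ever added.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(int(seed))
    adj = net.adjacency.copy()
    orig_deg = net.degrees
    for v in truth.resected_nodes:
        quota = int(round(fraction * orig_deg[v]))
        already = int(orig_deg[v] - adj[v].sum())
        todo = max(quota - already, 0)
        neighbors = np.flatnonzero(adj[v])
        if todo > 0 and neighbors.size:
            drop = rng.choice(neighbors, size=min(todo, neighbors.size), replace=False)
            adj[v, drop] = adj[drop, v] = 0
    return net.with_adjacency(adj)


def _incident_edges(adj: np.ndarray, sector: np.ndarray):
    """Undirected edges (i, j), i<j, with at least one endpoint in sector."""
    mask = np.zeros(adj.shape[0], dtype=bool)
    mask[np.asarray(sector, dtype=int)] = True
    i, j = np.nonzero(np.triu(adj, k=1))
    keep = mask[i] | mask[j]
    return list(zip(i[keep].tolist(), j[keep].tolist()))


def _degree_preserving_swaps(
    adj: np.ndarray,
    candidate_edges,
    target_changed: int,
    rng: np.random.Generator,
    max_attempts: int | None = None,
):
    """Double-edge swaps among ``candidate_edges`` until ``target_changed``
    edges differ from the original edge set (or the attempt cap is hit).

    A swap (a,b),(c,d) -> (a,d),(c,b) keeps every degree; swaps creating
    self-loops or multi-edges are rejected.  Returns the number of edges of
    the final graph absent from the original.
    """
    original = {(min(a, b), max(a, b)) for a, b in candidate_edges}
    edges = list(original)
    if max_attempts is None:
        max_attempts = 60 * max(target_changed, 1) + 500

    n_changed = 0
    attempts = 0
    current = set(edges)
    while n_changed < target_changed and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, len(edges), size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if rng.random() < 0.5:
            c, d = d, c
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b:
            continue
        if new1 in current or new2 in current:
            continue
        if adj[new1] or adj[new2]:  # collides with an edge outside the candidate set
            continue
        # apply swap
        old1, old2 = edges[k1], edges[k2]
        adj[old1] = adj[old1[::-1]] = 0
        adj[old2] = adj[old2[::-1]] = 0
        adj[new1] = adj[new1[::-1]] = 1
        adj[new2] = adj[new2[::-1]] = 1
        for old in (old1, old2):
            current.discard(old)
            if old not in original:
                n_changed -= 1
        for new in (new1, new2):
            current.add(new)
            if new not in original:
                n_changed += 1
        edges[k1], edges[k2] = new1, new2
    return n_changed


def apply_outcome_effect(
    net: Connectome,
    truth: GroundTruth,
    effect_size: float,
    group: str,
    seed: int,
) -> Connectome:
    """Plant the contralateral group effect in a pre-surgery network.

    For ``group == "poor"`` a fraction ``effect_size`` of the edges incident
    to the contralateral sector is redirected toward the resected sector by
    degree-preserving swaps: a sector edge (a, b) and a resected-sector edge
    (c, d) become (a, c) and (b, d).  This models an epileptogenic network
    that extends beyond the planned resection into the opposite hemisphere
    — the pre-surgery networks of poor-outcome patients carry abnormal
    contralateral-to-resection coupling, which the resection later severs.
    Favorable patients are returned unchanged; the degree sequence is
    preserved exactly; no edges are added or removed, only re-paired.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if group not in ("favorable", "poor"):
        raise ValueError(f"unknown outcome group {group!r}")
    if group == "favorable" or effect_size == 0:
        return net
    adj = net.adjacency.copy()
    contra = set(int(v) for v in truth.contralateral_sector)
    resec = set(int(v) for v in truth.resected_nodes)
    rng = np.random.default_rng(int(seed))

    def pool(sector, exclude):
        out = []
        for i, j in _incident_edges(adj, np.asarray(sorted(sector))):
            if i in exclude or j in exclude:
                continue
            # orient the sector endpoint first
            out.append((i, j) if i in sector else (j, i))
        return out

    pool_a = pool(contra, resec)  # (a in contra, b)
    target = int(round(effect_size * len(pool_a)))
    n_done, attempts = 0, 0
    max_attempts = 200 * max(target, 1) + 1000
    while n_done < target and attempts < max_attempts:
        attempts += 1
        pool_c = pool(resec, contra)  # (c in resected, d)
        if not pool_a or not pool_c:
            break
        a, b = pool_a[int(rng.integers(len(pool_a)))]
        c, d = pool_c[int(rng.integers(len(pool_c)))]
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, c] = adj[c, a] = 1
        adj[b, d] = adj[d, b] = 1
        pool_a = pool(contra, resec)
        n_done += 1
    return net.with_adjacency(adj)


def _subject_seeds(master_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(int(master_seed))
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def generate_cohort(config: SyntheticConfig, out_dir: str):
    """Write a complete on-disk cohort; returns (CohortTable, ground truths).

    Layout: ``nodes.csv``, ``cohort.csv``, ``networks/<subject>_{pre,post}.csv``
    and a ``ground_truth.json`` sidecar.  Controls are plain base networks;
    each patient's pre network is base + (poor-only) contralateral effect,
    and the post network is the pre network with the resection applied.
    Fully reproducible from ``config.seed``.
    """
    os.makedirs(os.path.join(out_dir, "networks"), exist_ok=True)
    n_pat = config.n_favorable + config.n_poor
    n_total = n_pat + config.n_controls
    # 3 derived seeds per subject: base graph, effect rewiring, resection
    seeds = _subject_seeds(config.seed, 3 * n_total)
    R = calibrate_disk_radius(config)
    n_left = int(round(config.side_mix * n_pat))
    outcomes = ["favorable"] * config.n_favorable + ["poor"] * config.n_poor
    # interleave outcomes across sides so both strata keep both classes
    order = sorted(range(n_pat), key=lambda t: (t % 2, t))
    sides = [""] * n_pat
    for pos, idx in enumerate(order):
        sides[idx] = "left" if pos < n_left else "right"

    records, truths = [], {}
    nodes_path = os.path.join(out_dir, "nodes.csv")
    first_net = None
    for s in range(n_total):
        base_seed, eff_seed, res_seed = seeds[3 * s : 3 * s + 3]
        if s < n_pat:
            sid = f"pat{s:03d}"
            side, outcome = sides[s], outcomes[s]
            net, truth = generate_base_connectome(config, base_seed, side, disk_radius=R)
            pre = apply_outcome_effect(net, truth, config.effect_size, outcome, eff_seed)
            post = apply_resection(pre, truth, config.resection_fraction, res_seed)
            pre_path = os.path.join("networks", f"{sid}_pre.csv")
            post_path = os.path.join("networks", f"{sid}_post.csv")
            write_connectome(os.path.join(out_dir, pre_path), pre)
            write_connectome(os.path.join(out_dir, post_path), post)
            records.append(
                CohortRecord(sid, "patient", side, outcome, pre_path, post_path)
            )
            first_net = first_net or pre
        else:
            sid = f"ctl{s - n_pat:03d}"
            net, truth = generate_base_connectome(config, base_seed, "left", disk_radius=R)
            pre_path = os.path.join("networks", f"{sid}_pre.csv")
            write_connectome(os.path.join(out_dir, pre_path), net)
            records.append(CohortRecord(sid, "control", "none", "none", pre_path, None))
            first_net = first_net or net
        truths[sid] = truth
    write_node_table(nodes_path, first_net)
    table = CohortTable(tuple(records))
    write_cohort(os.path.join(out_dir, "cohort.csv"), table)
    sidecar = {
        sid: {
            "true_radius": t.true_radius.tolist(),
            "true_angle": t.true_angle.tolist(),
            "resected_nodes": list(t.resected_nodes),
            "contralateral_sector": list(t.contralateral_sector),
            "side": t.side,
            "subject_seed": t.subject_seed,
        }
        for sid, t in truths.items()
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump({"config": asdict(config), "subjects": sidecar}, fh, indent=1)
    return table, truths
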