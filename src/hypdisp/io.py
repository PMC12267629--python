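"""Reading, writing and validating connectivity networks and cohort tables.

On-disk formats (all plain text):

* adjacency matrix — headerless CSV of 0/1 integers, N rows x N columns;
* edge list — two-column CSV of node labels, one undirected edge per row,
  read together with a node table;
* node table — CSV with columns ``node_id,hemisphere``; its row order fixes
  the node order shared by every network of a cohort;
* cohort table — CSV with columns
  ``subject_id,role,side,outcome,pre_path,post_path``.

Patients carry a surgery side (left/right), an outcome label
(favorable/poor) and both a pre- and a post-surgery network; healthy
controls carry a single network and no side or outcome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
ROLES = ("patient", "control")
SIDES = ("left", "right", "none")
OUTCOMES = ("favorable", "poor", "none")


class FormatError(ValueError):
    """Raised when an input file is structurally malformed."""


class ValidationError(ValueError):
    """Raised when an input is well-formed but violates a domain invariant."""


@dataclass(frozen=True)
class Connectome:
    """A labeled, binary, symmetric, loop-free graph on atlas nodes.

    Attributes
    ----------
    node_ids : tuple of str
        Unique node labels; their order is the canonical index order.
    hemisphere : tuple of str
        Per-node tag, ``"left"`` or ``"right"``.
    adjacency : ndarray of shape (N, N)
        Binary symmetric matrix with a zero diagonal.
    """

    node_ids: tuple
    hemisphere: tuple
    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValidationError("node_ids must be unique")
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise FormatError(f"adjacency must be square, got shape {adj.shape}")
        if adj.shape[0] != n:
            raise ValidationError(
                f"adjacency dimension {adj.shape[0]} != number of node ids {n}"
            )
        if len(self.hemisphere) != n:
            raise ValidationError("one hemisphere tag required per node")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValidationError(f"unknown hemisphere tag(s): {sorted(bad)}")
        adj = (np.asarray(adj, dtype=float) > 0).astype(np.int8)
        if not np.array_equal(adj, adj.T):
            i, j = np.argwhere(adj != adj.T)[0]
            raise ValidationError(
                f"adjacency is not symmetric, e.g. entries ({i},{j}) vs ({j},{i})"
            )
        np.fill_diagonal(adj, 0)
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def with_adjacency(self, adjacency: np.ndarray) -> "Connectome":
        """Same nodes, new adjacency (validated)."""
        return Connectome(self.node_ids, self.hemisphere, adjacency)

    def edge_set(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return {(int(a), int(b)) for a, b in zip(i, j)}


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    role: str
    side: str
    outcome: str
    pre_path: str
    post_path: str | None


@dataclass(frozen=True)
class CohortTable:
    """Validated roster of patients and controls with their network files."""

    records: tuple

    def __post_init__(self):
        recs = tuple(self.records)
        ids = [r.subject_id for r in recs]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate subject_id(s): {sorted(dupes)}")
        for r in recs:
            if r.role not in ROLES:
                raise ValidationError(f"{r.subject_id}: unknown role {r.role!r}")
            if r.role == "patient":
                if r.side not in ("left", "right"):
                    raise ValidationError(
                        f"patient {r.subject_id}: side must be left or right"
                    )
                if r.outcome not in ("favorable", "poor"):
                    raise ValidationError(
                        f"patient {r.subject_id}: outcome must be favorable or poor"
                    )
                if not r.pre_path or not r.post_path:
                    raise ValidationError(
                        f"patient {r.subject_id}: needs both pre_path and post_path"
                    )
            else:
                if r.side != "none":
                    raise ValidationError(f"control {r.subject_id}: side must be none")
                if r.outcome != "none":
                    raise ValidationError(
                        f"control {r.subject_id}: outcome must be none"
                    )
                if not r.pre_path:
                    raise ValidationError(f"control {r.subject_id}: needs pre_path")
        object.__setattr__(self, "records", recs)

    @property
    def patients(self) -> tuple:
        return tuple(r for r in self.records if r.role == "patient")

    @property
    def controls(self) -> tuple:
        return tuple(r for r in self.records if r.role == "control")


def read_node_table(path) -> tuple[tuple, tuple]:
    """Read a ``node_id,hemisphere`` CSV; returns (node_ids, hemisphere)."""
    df = pd.read_csv(path, dtype=str)
    required = {"node_id", "hemisphere"}
    if not required.issubset(df.columns):
        raise FormatError(f"node table {path} must have columns {sorted(required)}")
    return tuple(df["node_id"]), tuple(df["hemisphere"])


def write_node_table(path, net: Connectome) -> None:
    pd.DataFrame({"node_id": net.node_ids, "hemisphere": net.hemisphere}).to_csv(
        path, index=False
    )


def read_connectome(path, node_table=None) -> Connectome:
    """Read a network from a square adjacency CSV or a 2-column edge list.

    A file whose first row parses as all-numeric with N columns matching the
    row count is read as an adjacency matrix; otherwise it is read as an
    edge list, which requires ``node_table`` for node order and hemispheres.
    Nonzero entries are binarized; asymmetric matrices are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if node_table is None:
        raise ValidationError(
            "a node table (node_id, hemisphere) is required to read any network"
        )
    node_ids, hemisphere = (
        node_table if isinstance(node_table, tuple) else read_node_table(node_table)
    )
    try:
        mat = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        numeric = True
    except ValueError:
        numeric = False
    if numeric:
        if mat.shape[0] != mat.shape[1]:
            raise FormatError(
                f"{path}: adjacency must be square, got {mat.shape[0]}x{mat.shape[1]}"
            )
        return Connectome(node_ids, hemisphere, mat)
    # edge list
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: edge list must have exactly 2 columns")
    index = {n: i for i, n in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=np.int8)
    for a, b in df.itertuples(index=False):
        if a not in index or b not in index:
            raise ValidationError(f"{path}: edge references unknown node {a!r} or {b!r}")
        i, j = index[a], index[b]
        if i == j:
            raise ValidationError(f"{path}: self-loop on node {a!r}")
        adj[i, j] = adj[j, i] = 1
    return Connectome(node_ids, hemisphere, adj)


def write_connectome(path, net: Connectome) -> None:
    """Write the adjacency as a headerless CSV of 0/1 integers."""
    np.savetxt(path, net.adjacency, fmt="%d", delimiter=",")


def read_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV; referenced network files must exist.

    Relative network paths are resolved against the cohort file's directory.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValidationError(f"cohort file {path} is empty")
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"subject_id", "role", "side", "outcome", "pre_path", "post_path"}
    if not required.issubset(df.columns):
        raise FormatError(f"cohort file must have columns {sorted(required)}")
    if df.empty:
        raise ValidationError(f"cohort file {path} contains no records")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        if not p:
            return None
        return p if os.path.isabs(p) else os.path.join(base, p)

    records = []
    for row in df.itertuples(index=False):
        rec = CohortRecord(
            subject_id=row.subject_id,
            role=row.role,
            side=row.side or "none",
            outcome=row.outcome or "none",
            pre_path=resolve(row.pre_path),
            post_path=resolve(row.post_path),
        )
        records.append(rec)
    table = CohortTable(tuple(records))
    for r in table.records:
        for p in (r.pre_path, r.post_path):
            if p and not os.path.exists(p):
                raise ValidationError(f"{r.subject_id}: network file not found: {p}")
    return table


def write_cohort(path, table: CohortTable) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "role": r.role,
            "side": r.side,
            "outcome": r.outcome,
            "pre_path": r.pre_path or "",
            "post_path": r.post_path or "",
        }
        for r in table.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def check_same_nodes(nets) -> None:
    """All networks of one cohort must share node_ids in identical order."""
    nets = list(nets)
    first = nets[0].node_ids
    for net in nets[1:]:
        if net.node_ids != first:
            raise ValidationError("networks of one cohort must share node order")
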