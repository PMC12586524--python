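"""Core data model for federated multi-label graph datasets.

A federation consists of K clients ("shards"), each holding attributed
graphs that carry a binary label vector over a shared, ordered label
space of C classes. The on-disk container is JSON-lines: a header record
per client followed by one record per graph, with adjacency stored as an
undirected edge list (each edge stored once, 0-based indices).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSpace",
    "MultiLabelGraph",
    "ClientShard",
    "FederatedDataset",
    "DatasetParseError",
    "DatasetSchemaError",
    "read_dataset",
    "write_dataset",
    "load_molecular_csv",
]


class DatasetParseError(ValueError):
    """Malformed container record (names the offending line)."""


class DatasetSchemaError(ValueError):
    """Record violates the container schema / dataset invariants."""


@dataclass(frozen=True)
class LabelSpace:
    """Ordered, shared label space of C classes."""

    names: tuple

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) == 0:
            raise DatasetSchemaError("label space must contain at least one label")
        if len(set(self.names)) != len(self.names):
            raise DatasetSchemaError("label names must be unique")

    @property
    def C(self) -> int:
        return len(self.names)


@dataclass
class MultiLabelGraph:
    """One attributed graph with a C-length binary label vector."""

    graph_id: str
    adjacency: np.ndarray  # symmetric, nonnegative, zero diagonal (n, n)
    node_features: np.ndarray  # (n, d_x)
    labels: np.ndarray  # (C,) in {0, 1}

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.adjacency.shape[0]
        if n < 1 or self.adjacency.shape != (n, n):
            raise DatasetSchemaError(f"graph {self.graph_id}: adjacency must be square, n >= 1")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise DatasetSchemaError(f"graph {self.graph_id}: adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise DatasetSchemaError(f"graph {self.graph_id}: self-loops are not allowed")
        if np.any(self.adjacency < 0):
            raise DatasetSchemaError(f"graph {self.graph_id}: edge weights must be nonnegative")
        if self.node_features.ndim != 2 or self.node_features.shape[0] != n:
            raise DatasetSchemaError(f"graph {self.graph_id}: node_features must be (n, d_x)")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise DatasetSchemaError(f"graph {self.graph_id}: labels must be binary")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def __eq__(self, other):
        return (
            isinstance(other, MultiLabelGraph)
            and self.graph_id == other.graph_id
            and np.array_equal(self.adjacency, other.adjacency)
            and np.array_equal(self.node_features, other.node_features)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class ClientShard:
    """One client's private collection of graphs."""

    client_id: str
    graphs: list
    label_space: LabelSpace

    def __post_init__(self):
        if not self.graphs:
            raise DatasetSchemaError(f"client {self.client_id}: shard must be nonempty")
        for g in self.graphs:
            if g.labels.shape[0] != self.label_space.C:
                raise DatasetSchemaError(
                    f"client {self.client_id}, graph {g.graph_id}: label vector length "
                    f"{g.labels.shape[0]} != C={self.label_space.C}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.graphs)

    def __eq__(self, other):
        return (
            isinstance(other, ClientShard)
            and self.client_id == other.client_id
            and self.label_space == other.label_space
            and self.graphs == other.graphs
        )


@dataclass
class FederatedDataset:
    """K client shards over one shared label space."""

    shards: list
    label_space: LabelSpace = field(default=None)

    def __post_init__(self):
        if not self.shards:
            raise DatasetSchemaError("federation must have at least one client")
        if self.label_space is None:
            self.label_space = self.shards[0].label_space
        ids = [s.client_id for s in self.shards]
        if len(set(ids)) != len(ids):
            raise DatasetSchemaError("client ids must be unique")
        for s in self.shards:
            if s.label_space != self.label_space:
                raise DatasetSchemaError(
                    f"client {s.client_id} label space differs from the federation's"
                )

    @property
    def K(self) -> int:
        return len(self.shards)

    @property
    def total_samples(self) -> int:
        return sum(s.n_samples for s in self.shards)

    def __eq__(self, other):
        return (
            isinstance(other, FederatedDataset)
            and self.label_space == other.label_space
            and self.shards == other.shards
        )


# --------------------------------------------------------------------------
# JSON-lines container
# --------------------------------------------------------------------------

def _edges_from_adjacency(A: np.ndarray) -> list:
    i_idx, j_idx = np.nonzero(np.triu(A, k=1))
    return [[int(i), int(j), float(A[i, j])] for i, j in zip(i_idx, j_idx)]


def _adjacency_from_edges(edges, n: int, where: str) -> np.ndarray:
    A = np.zeros((n, n), dtype=np.float64)
    for e in edges:
        if len(e) != 3:
            raise DatasetSchemaError(f"{where}: edge must be [i, j, w], got {e!r}")
        i, j, w = int(e[0]), int(e[1]), float(e[2])
        if i == j:
            raise DatasetSchemaError(f"{where}: self-loop ({i}, {j}) not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise DatasetSchemaError(f"{where}: edge ({i}, {j}) out of range for n={n}")
        A[i, j] = w
        A[j, i] = w
    return A


def read_dataset(path) -> FederatedDataset:
    """Read the JSON-lines container. Clients and graphs keep file order."""
    shards = []
    label_space = None
    cur_client = None
    cur_graphs: list = []

    def flush():
        nonlocal cur_client, cur_graphs
        if cur_client is not None:
            shards.append(ClientShard(cur_client, cur_graphs, label_space))
        cur_client, cur_graphs = None, []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DatasetParseError(f"line {lineno}: malformed JSON record: {exc}") from exc
            if "client_id" in rec:
                flush()
                names = tuple(rec.get("label_names", ()))
                space = LabelSpace(names)
                if label_space is None:
                    label_space = space
                elif space != label_space:
                    raise DatasetSchemaError(
                        f"line {lineno}: client {rec['client_id']} label_names differ "
                        "from the federation's label space"
                    )
                cur_client = str(rec["client_id"])
            elif "graph_id" in rec:
                if cur_client is None:
                    raise DatasetSchemaError(f"line {lineno}: graph record before any client header")
                where = f"line {lineno} (graph {rec['graph_id']})"
                try:
                    n = int(rec["n"])
                    y = np.asarray(rec["y"], dtype=np.int64)
                    x = np.asarray(rec["x"], dtype=np.float64)
                    edges = rec["edges"]
                except KeyError as exc:
                    raise DatasetSchemaError(f"{where}: missing field {exc}") from exc
                if y.shape[0] != label_space.C:
                    raise DatasetSchemaError(
                        f"{where}: label vector length {y.shape[0]} != C={label_space.C}"
                    )
                A = _adjacency_from_edges(edges, n, where)
                cur_graphs.append(MultiLabelGraph(str(rec["graph_id"]), A, x, y))
            else:
                raise DatasetParseError(
                    f"line {lineno}: record is neither a client header nor a graph"
                )
    flush()
    if not shards:
        raise DatasetSchemaError("container holds no client records")
    return FederatedDataset(shards, label_space)


def write_dataset(ds: FederatedDataset, path) -> None:
    """Write the JSON-lines container; round-trips exactly through read_dataset."""
    with open(path, "w", encoding="utf-8") as fh:
        for shard in ds.shards:
            fh.write(json.dumps({
                "client_id": shard.client_id,
                "label_names": list(ds.label_space.names),
            }) + "\n")
            for g in shard.graphs:
                fh.write(json.dumps({
                    "graph_id": g.graph_id,
                    "n": g.n_nodes,
                    "edges": _edges_from_adjacency(g.adjacency),
                    "x": g.node_features.tolist(),
                    "y": g.labels.tolist(),
                }) + "\n")


# --------------------------------------------------------------------------
# Molecular CSV loader (Tox21 / SIDER / MUV style)
# --------------------------------------------------------------------------

_ATOM_FEATURES = 7  # Z, degree, formal charge, #H, aromatic, in-ring, mass/100


def _atom_features(atom) -> list:
    return [
        float(atom.GetAtomicNum()),
        float(atom.GetDegree()),
        float(atom.GetFormalCharge()),
        float(atom.GetTotalNumHs()),
        float(atom.GetIsAromatic()),
        float(atom.IsInRing()),
        atom.GetMass() / 100.0,
    ]


def load_molecular_csv(path, smiles_col: str, label_cols) -> ClientShard:
    """Load a molecular CSV (one SMILES column, C binary/NA label columns).

    Atoms become nodes with simple descriptor features, bonds become
    unit-weight edges. Missing labels are imputed to 0 (absent) and
    unparsable SMILES rows are skipped; both counts are logged.
    """
    import pandas as pd
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")

    df = pd.read_csv(path)
    label_cols = list(label_cols)
    missing = [c for c in [smiles_col] + label_cols if c not in df.columns]
    if missing:
        raise DatasetSchemaError(f"molecular CSV is missing columns: {missing}")

    space = LabelSpace(tuple(label_cols))
    graphs = []
    n_skipped = 0
    n_imputed = 0
    for idx, row in df.iterrows():
        mol = Chem.MolFromSmiles(str(row[smiles_col]))
        if mol is None or mol.GetNumAtoms() == 0:
            n_skipped += 1
            continue
        n = mol.GetNumAtoms()
        A = np.zeros((n, n), dtype=np.float64)
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            A[i, j] = A[j, i] = 1.0
        x = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
        y = np.zeros(space.C, dtype=np.int64)
        for k, col in enumerate(label_cols):
            v = row[col]
            if pd.isna(v):
                n_imputed += 1
            else:
                y[k] = int(float(v))
        graphs.append(MultiLabelGraph(f"row{idx}", A, x, y))
    logger.info(
        "load_molecular_csv: %d graphs, %d rows skipped (unparsable SMILES), "
        "%d missing labels imputed to 0", len(graphs), n_skipped, n_imputed,
    )
    if not graphs:
        raise DatasetSchemaError("no parsable SMILES rows in molecular CSV")
    shard = ClientShard("molecular_csv", graphs, space)
    shard.n_skipped = n_skipped
    shard.n_imputed = n_imputed
    return shard
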