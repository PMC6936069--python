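"""Weighted undirected networks, multi-view collections, and connectivity-network filters.

A functional brain network (FBN) is represented as a square symmetric weight
matrix over an ordered node set (one node per region of interest).  Raw
networks carry signed Pearson correlations; :func:`preprocess_fbn` applies the
standard filtering used before module detection: negative weights are removed,
then weights below a threshold (default 0.35) are removed, keeping the
threshold value itself.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedNetwork",
    "MultiViewNetworkSet",
    "read_network",
    "write_network",
    "read_node_table",
    "write_node_table",
    "preprocess_fbn",
    "is_connected",
    "average_network",
    "DEFAULT_THRESHOLD",
    "SYMMETRY_TOL",
]

#: Edge-weight cutoff used when filtering correlation networks.
DEFAULT_THRESHOLD = 0.35

#: Maximum |A - A.T| allowed when reading a dense matrix claimed symmetric.
SYMMETRY_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class WeightedNetwork:
    """A weighted undirected network on an ordered node set.

    Parameters
    ----------
    node_ids : tuple of str
        Unique node identifiers, in matrix order.
    weights : ndarray of shape (N, N)
        Symmetric weight matrix with zero diagonal.  Entries may be negative
        (raw signed correlations); filtered networks are nonnegative.
    """

    node_ids: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_ids", tuple(str(i) for i in self.node_ids))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if len(self.node_ids) != w.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for a {w.shape[0]}-node matrix"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if np.isnan(w).any():
            raise ValueError("weight matrix contains NaN entries")
        if not np.allclose(w, w.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise ValueError("weight matrix is not symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 0.0:
            raise ValueError("diagonal entries must be zero")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def is_nonnegative(self) -> bool:
        return bool((self.weights >= 0).all())

    def index_of(self, node_id) -> int:
        return self.node_ids.index(str(node_id))

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        return WeightedNetwork(self.node_ids, weights)


@dataclasses.dataclass(frozen=True)
class MultiViewNetworkSet:
    """A collection of same-size networks over one shared node ordering.

    Each view is typically one subject's functional network; the views are
    jointly factorized to find a shared module structure.
    """

    views: tuple

    def __post_init__(self):
        views = tuple(self.views)
        object.__setattr__(self, "views", views)
        if len(views) < 1:
            raise ValueError("a multi-view set needs at least one view")
        ref = views[0].node_ids
        for v in views[1:]:
            if v.node_ids != ref:
                raise ValueError("all views must share one node ordering")

    @classmethod
    def from_matrices(cls, matrices: Sequence[np.ndarray], node_ids=None):
        mats = [np.asarray(m, dtype=float) for m in matrices]
        if not mats:
            raise ValueError("a multi-view set needs at least one view")
        if node_ids is None:
            node_ids = [str(i) for i in range(mats[0].shape[0])]
        return cls(tuple(WeightedNetwork(node_ids, m) for m in mats))

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_nodes(self) -> int:
        return self.views[0].n_nodes

    @property
    def node_ids(self) -> tuple:
        return self.views[0].node_ids

    def matrices(self) -> list:
        return [v.weights for v in self.views]

    def preprocess(self, threshold: float = DEFAULT_THRESHOLD) -> "MultiViewNetworkSet":
        return MultiViewNetworkSet(
            tuple(preprocess_fbn(v, threshold) for v in self.views)
        )

    def average(self) -> WeightedNetwork:
        return average_network(self)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_network(path, format: str = "dense", node_ids=None) -> WeightedNetwork:
    """Read a weighted network from a text file.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"dense", "edgelist"}
        ``dense``: whitespace/comma-delimited square matrix, optional header
        row of node ids.  ``edgelist``: three columns (source, target, weight),
        symmetrized by mirroring; duplicate rows must agree.
    node_ids : sequence of str, optional
        For edge lists, the declared node set (nodes absent from the list get
        zero rows); ignored for dense files with a header.
    """
    path = Path(path)
    if format == "dense":
        return _read_dense(path, node_ids)
    if format == "edgelist":
        return _read_edgelist(path, node_ids)
    raise ValueError(f"unknown network format {format!r}")


def _read_dense(path: Path, node_ids) -> WeightedNetwork:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty network file")
    first = lines[0].replace(",", " ").split()
    header = None
    if not all(_looks_numeric(tok) for tok in first):
        header = first
        lines = lines[1:]
    data = pd.read_csv(
        io.StringIO("\n".join(lines)), sep=r"[,\s]+", engine="python", header=None
    )
    w = data.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: dense matrix is not square (shape {w.shape})")
    if np.isnan(w).any():
        raise ValueError(f"{path}: matrix contains NaN entries")
    if np.abs(w - w.T).max(initial=0.0) > SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance {SYMMETRY_TOL}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if header is not None:
        ids = header
    elif node_ids is not None:
        ids = list(node_ids)
    else:
        ids = [str(i) for i in range(w.shape[0])]
    return WeightedNetwork(ids, w)


def _read_edgelist(path: Path, node_ids) -> WeightedNetwork:
    df = pd.read_csv(path, sep=r"[,\t\s]+", engine="python", header=None, dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: edge list must have 3 columns, got {df.shape[1]}")
    if not _looks_numeric(df.iloc[0, 2]):
        df = df.iloc[1:].reset_index(drop=True)
    src = df.iloc[:, 0].astype(str)
    dst = df.iloc[:, 1].astype(str)
    wts = df.iloc[:, 2].astype(float)
    if wts.isna().any():
        raise ValueError(f"{path}: NaN edge weights")
    if node_ids is None:
        ids = sorted(set(src) | set(dst))
    else:
        ids = [str(i) for i in node_ids]
        missing = (set(src) | set(dst)) - set(ids)
        if missing:
            raise ValueError(f"{path}: edge endpoints not in declared nodes: {missing}")
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    seen: dict = {}
    for s, d, x in zip(src, dst, wts):
        i, j = idx[s], idx[d]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen and abs(seen[key] - x) > 1e-12:
            raise ValueError(
                f"{path}: conflicting duplicate edge {s}-{d}: {seen[key]} vs {x}"
            )
        seen[key] = x
        w[i, j] = w[j, i] = x
    return WeightedNetwork(ids, w)


def write_network(net: WeightedNetwork, path, format: str = "dense", header: bool = False):
    """Write a network as dense delimited text or a TSV edge list."""
    path = Path(path)
    if format == "dense":
        with path.open("w") as fh:
            if header:
                fh.write("\t".join(net.node_ids) + "\n")
            np.savetxt(fh, net.weights, delimiter="\t", fmt="%.10g")
    elif format == "edgelist":
        rows = []
        w = net.weights
        for i in range(net.n_nodes):
            for j in range(i + 1, net.n_nodes):
                if w[i, j] != 0:
                    rows.append((net.node_ids[i], net.node_ids[j], w[i, j]))
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_node_table(path) -> pd.DataFrame:
    """Read a node metadata TSV with columns node_id[, x, y, z][, label].

    Coordinates, when present, must be all present or all absent per row
    (MNI-152 mm convention for real imaging data).
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    if "node_id" not in df.columns:
        raise ValueError("node table needs a 'node_id' column")
    if df["node_id"].duplicated().any():
        raise ValueError("node ids must be unique")
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if coord_cols:
        if len(coord_cols) != 3:
            raise ValueError("coordinates need all of x, y, z columns")
        present = df[coord_cols].notna()
        mixed = present.any(axis=1) & ~present.all(axis=1)
        if mixed.any():
            bad = df.loc[mixed, "node_id"].tolist()
            raise ValueError(f"rows with partial coordinates: {bad}")
    return df


def write_node_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def preprocess_fbn(net: WeightedNetwork, threshold: float = DEFAULT_THRESHOLD) -> WeightedNetwork:
    """Filter a correlation network for module detection.

    Negative weights are removed first, then weights strictly below
    ``threshold``; a weight equal to the threshold survives.  The diagonal is
    forced to zero.  Idempotent pure filter.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    w = net.weights.copy()
    w[w < 0] = 0.0
    w[w < threshold] = 0.0
    np.fill_diagonal(w, 0.0)
    return net.with_weights(w)


def is_connected(net: WeightedNetwork) -> bool:
    """True iff the graph on edges with positive weight is one component."""
    g = nx.from_numpy_array((net.weights > 0).astype(int))
    return nx.is_connected(g)


def average_network(views) -> WeightedNetwork:
    """Element-wise mean of the views (expected already preprocessed)."""
    if isinstance(views, MultiViewNetworkSet):
        nets = views.views
    else:
        nets = tuple(views)
    if not nets:
        raise ValueError("cannot average an empty view set")
    ref = nets[0].node_ids
    for v in nets[1:]:
        if v.node_ids != ref:
            raise ValueError("all views must share one node ordering")
    mean = np.mean([v.weights for v in nets], axis=0)
    return WeightedNetwork(ref, mean)
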