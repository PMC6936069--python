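"""Module-quality indices for weighted partitions and partition agreement.

For a partition (M_1, ..., M_K) of a weighted network A, define per module

    V_k = sum_{i in M_k} sum_j A_ij     (module volume, both orientations)
    W_k = sum_{i in M_k, j in M_k} A_ij (intra-module weight, both orientations)

and T = sum_ij A_ij.  With hats denoting division by T:

* modularity  = sum_k (W^_k - V^_k^2)          -- Newman-Girvan weighted form
* conductance = mean_k W_k / V_k               -- compactness of modules
* coverage    = sum_k W^_k                     -- intra-module weight fraction

W_k and V_k are normalized by T so the indices land in their conventional
unit ranges; both conventions count each undirected edge in both
orientations, so the normalization cancels consistently.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Partition",
    "ModuleQuality",
    "modularity",
    "conductance",
    "coverage",
    "module_quality",
    "adjusted_rand_index",
    "quality_scan",
]


@dataclasses.dataclass(frozen=True)
class Partition:
    """Assignment of each node to exactly one of ``n_modules`` modules."""

    labels: np.ndarray
    n_modules: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_modules):
            raise ValueError("labels out of range 0..n_modules-1")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def module_nodes(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules)

    def empty_modules(self) -> list:
        return [k for k, s in enumerate(self.sizes()) if s == 0]


@dataclasses.dataclass(frozen=True)
class ModuleQuality:
    """The three indices plus the per-module fractions they are built from."""

    modularity: float
    conductance: float
    coverage: float
    per_module_W: np.ndarray  # W_k / T
    per_module_V: np.ndarray  # V_k / T


def _as_matrix(net) -> np.ndarray:
    w = getattr(net, "weights", net)
    return np.asarray(w, dtype=float)


def _module_sums(A: np.ndarray, p: Partition):
    """Return (W_k, V_k, T), unnormalized, both orientations counted."""
    if p.n_nodes != A.shape[0]:
        raise ValueError("partition does not cover the network's nodes")
    T = A.sum()
    K = p.n_modules
    degrees = A.sum(axis=1)
    V = np.zeros(K)
    W = np.zeros(K)
    for k in range(K):
        idx = p.module_nodes(k)
        V[k] = degrees[idx].sum()
        W[k] = A[np.ix_(idx, idx)].sum()
    return W, V, T


def modularity(net, p: Partition) -> float:
    """Weighted modularity sum_k (W^_k - V^_k^2); in [-1, 1)."""
    A = _as_matrix(net)
    W, V, T = _module_sums(A, p)
    if T == 0:
        raise ValueError("empty network: total weight is zero")
    return float(((W / T) - (V / T) ** 2).sum())


def conductance(net, p: Partition) -> float:
    """Mean over non-empty modules of W_k / V_k; in [0, 1].

    Modules with zero volume are excluded from the mean with a warning.
    """
    A = _as_matrix(net)
    W, V, _ = _module_sums(A, p)
    ok = V > 0
    if not ok.any():
        raise ValueError("no module has positive volume")
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} module(s) with zero volume excluded from conductance",
            stacklevel=2,
        )
    return float((W[ok] / V[ok]).mean())


def coverage(net, p: Partition) -> float:
    """Fraction of total weight that is intra-module; in [0, 1]."""
    A = _as_matrix(net)
    W, _, T = _module_sums(A, p)
    if T == 0:
        raise ValueError("empty network: total weight is zero")
    return float(W.sum() / T)


def module_quality(net, p: Partition) -> ModuleQuality:
    """All three indices in one pass over the network."""
    A = _as_matrix(net)
    W, V, T = _module_sums(A, p)
    if T == 0:
        raise ValueError("empty network: total weight is zero")
    What, Vhat = W / T, V / T
    ok = V > 0
    return ModuleQuality(
        modularity=float((What - Vhat**2).sum()),
        conductance=float((W[ok] / V[ok]).mean()),
        coverage=float(What.sum()),
        per_module_W=What,
        per_module_V=Vhat,
    )


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions cover different node sets")
    return float(adjusted_rand_score(p1.labels, p2.labels))


def quality_scan(
    views,
    K_values: Sequence[int],
    alpha_values: Sequence[float],
    runs: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Scan module count K and sparsity weight alpha over a grid.

    For each (K, alpha) cell the joint factorization is fitted ``runs`` times
    from random starts, the representative run (highest mean pairwise ARI to
    the others) is kept, and the three indices are reported twice: averaged
    over per-view evaluations and on the element-wise average network.

    Returns a tidy DataFrame with columns
    (K, alpha, eval_mode, modularity, conductance, coverage).
    """
    from .jsnmf import JSNMF  # local import: jsnmf depends on this module
    from .networks import average_network

    rows = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(len(list(K_values)) * len(list(alpha_values)))
    i = 0
    for K in K_values:
        for alpha in alpha_values:
            model = JSNMF(views, n_modules=K, alpha=alpha, **fit_kwargs)
            if runs >= 2:
                restarts = model.fit_restarts(n_runs=runs, seed=int(cell_seeds[i]))
                part = restarts.representative.partition
            else:
                part = model.fit(seed=int(cell_seeds[i])).partition
            i += 1
            per_view = [module_quality(v, part) for v in model.views.views]
            rows.append(
                dict(
                    K=K,
                    alpha=alpha,
                    eval_mode="individual_mean",
                    modularity=float(np.mean([q.modularity for q in per_view])),
                    conductance=float(np.mean([q.conductance for q in per_view])),
                    coverage=float(np.mean([q.coverage for q in per_view])),
                )
            )
            avg_q = module_quality(average_network(model.views), part)
            rows.append(
                dict(
                    K=K,
                    alpha=alpha,
                    eval_mode="average_network",
                    modularity=avg_q.modularity,
                    conductance=avg_q.conductance,
                    coverage=avg_q.coverage,
                )
            )
    return pd.DataFrame(rows)
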