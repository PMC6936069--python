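"""Joint symmetric non-negative matrix factorization of multi-view networks.

Given n symmetric nonnegative adjacency matrices A^(v) over one shared node
set, the model seeks a single nonnegative indicator matrix H (N x K) and
per-view nonnegative mixing matrices S^(v) (K x K) minimizing

    O = sum_v || A^(v) - H S^(v) H^T ||_F^2 + 4 alpha sum_k |h_k|_1,

with the L1 column penalty encouraging a sparse, near-indicator H.  The
optimizer alternates an exact least-squares solve for each S^(v),

    S^(v) = (H^T H)^{-1} H^T A^(v) H (H^T H)^{-1},   clipped at zero,

with the KKT-derived multiplicative update for H,

    H <- H * [sum_v A^(v) H S^(v)] / [sum_v H S^(v) H^T H S^(v) + alpha E],

where E is the all-ones N x K matrix.  The multiplicative form preserves
nonnegativity and leaves exact zeros fixed; the alpha E term enters the
denominator so it shrinks H, acting as the sparsity penalty.

Nodes are assigned to modules from the column-normalized H (each column
scaled so its maximum is 1, balancing module sizes): node i joins the module
whose normalized H entry in row i is largest.

The API follows the model/results idiom: build a :class:`JSNMF` model from
the data, call :meth:`JSNMF.fit` (or :meth:`JSNMF.fit_restarts` for multiple
random starts with representative-run selection) and inspect the returned
results object.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

from .metrics import Partition, adjusted_rand_index
from .networks import MultiViewNetworkSet, WeightedNetwork

__all__ = [
    "JSNMF",
    "JSNMFResults",
    "JSNMFRestarts",
    "objective",
    "update_S",
    "update_H",
    "normalize_and_assign",
    "select_representative_run",
]

logger = logging.getLogger(__name__)

#: Stabilizer added to multiplicative-update denominators.
DEFAULT_EPS = 1e-12


def objective(A_list: Sequence[np.ndarray], H: np.ndarray, S_list, alpha: float) -> float:
    """Penalized joint factorization objective; nonnegative by construction."""
    if len(A_list) != len(S_list):
        raise ValueError("one S matrix per view is required")
    total = 0.0
    for A, S in zip(A_list, S_list):
        R = A - H @ S @ H.T
        total += float(np.sum(R * R))
    return total + 4.0 * alpha * float(H.sum())


def update_S(A: np.ndarray, H: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Closed-form least-squares S for one view, clipped to be nonnegative.

    Solves grad_S ||A - H S H^T||_F^2 = 0, i.e.
    S = (H^T H)^{-1} H^T A H (H^T H)^{-1}; a rank-deficient H^T H falls back
    to the pseudo-inverse with a warning.  Negative entries of the
    unconstrained solution are clipped at zero; clipping that moves any entry
    by more than 1e-8 is logged.
    """
    G = H.T @ H
    if np.linalg.cond(G) > 1.0 / max(eps, 1e-15):
        warnings.warn("H^T H is rank-deficient; using pseudo-inverse", stacklevel=2)
        Ginv = np.linalg.pinv(G)
    else:
        Ginv = np.linalg.inv(G)
    S = Ginv @ (H.T @ A @ H) @ Ginv
    S = (S + S.T) / 2.0  # A symmetric => S symmetric; remove numerical skew
    if S.min(initial=0.0) < -1e-8:
        logger.info("clipped negative S entries (min %.3e)", S.min())
    return np.maximum(S, 0.0)


def update_H(
    A_list: Sequence[np.ndarray],
    H: np.ndarray,
    S_list,
    alpha: float,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """One multiplicative update of the shared indicator H.

    Zero entries of H stay zero; the output is nonnegative whenever the
    inputs are.
    """
    num = np.zeros_like(H)
    den = np.zeros_like(H)
    for A, S in zip(A_list, S_list):
        HS = H @ S
        num += A @ HS
        den += HS @ (H.T @ HS)
    return H * num / (den + alpha + eps)


def normalize_and_assign(H: np.ndarray):
    """Column-normalize H to max 1 and assign each node to its argmax module.

    Ties go to the smallest module index.  Raises on an all-zero column
    (degenerate factorization).
    """
    col_max = H.max(axis=0)
    dead = np.flatnonzero(col_max == 0)
    if dead.size:
        raise ValueError(f"degenerate factorization: all-zero H column(s) {dead.tolist()}")
    H_norm = H / col_max
    labels = np.argmax(H_norm, axis=1)  # argmax returns the first (smallest) index on ties
    part = Partition(labels, n_modules=H.shape[1])
    if part.empty_modules():
        logger.info("partition has empty modules: %s", part.empty_modules())
    return H_norm, part


def select_representative_run(partitions: Sequence[Partition]) -> int:
    """Index of the run most similar (mean pairwise ARI) to all other runs.

    Ties break to the smallest index.
    """
    m = len(partitions)
    if m < 2:
        raise ValueError("need at least 2 runs to select a representative")
    ari = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ari[i, j] = ari[j, i] = adjusted_rand_index(partitions[i], partitions[j])
    mean_ari = ari.sum(axis=1) / (m - 1)
    return int(np.argmax(mean_ari))


def _coerce_views(views) -> MultiViewNetworkSet:
    if isinstance(views, MultiViewNetworkSet):
        return views
    views = list(views)
    if views and isinstance(views[0], WeightedNetwork):
        return MultiViewNetworkSet(tuple(views))
    return MultiViewNetworkSet.from_matrices(views)


class JSNMF:
    """Joint symmetric NMF model for a set of networks sharing one node set.

    Parameters
    ----------
    views : MultiViewNetworkSet, sequence of WeightedNetwork, or sequence of ndarray
        Symmetric nonnegative adjacency matrices (preprocessed networks).
    n_modules : int
        Number of modules K, 1 <= K <= N.
    alpha : float
        Sparsity regularization weight (>= 0).
    max_iter : int
        Iteration cap; one iteration is all n S-updates then one H-update.
    tol : float
        Relative-objective convergence tolerance.
    eps : float
        Stabilizer added to multiplicative denominators.
    warmup_iter : int
        Initialization-refinement iterations run before the alternating
        phase: multiplicative H updates with every S^(v) fixed at the
        identity and no sparsity penalty (i.e. plain multi-view symmetric
        NMF).  The free mixing matrices S^(v) make merged-module local
        minima attractive from a fully random start; aligning the columns
        of H with the data first avoids those basins while leaving the
        converged solution a fixed point of the alternating updates.
    """

    def __init__(
        self,
        views,
        n_modules: int,
        alpha: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        eps: float = DEFAULT_EPS,
        warmup_iter: int = 100,
    ):
        self.views = _coerce_views(views)
        N = self.views.n_nodes
        if not 1 <= n_modules <= N:
            raise ValueError(f"n_modules must be in 1..{N}, got {n_modules}")
        if alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if tol <= 0 or eps <= 0:
            raise ValueError("tol and eps must be positive")
        for v in self.views.views:
            if not v.is_nonnegative:
                raise ValueError(
                    "views must be nonnegative; preprocess raw correlation networks first"
                )
        if warmup_iter < 0:
            raise ValueError("warmup_iter must be nonnegative")
        self.n_modules = int(n_modules)
        self.alpha = float(alpha)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.eps = float(eps)
        self.warmup_iter = int(warmup_iter)

    def fit(self, seed: int | None = None, init_H: np.ndarray | None = None) -> "JSNMFResults":
        """Run the alternating optimization from one random (or given) start."""
        A_list = self.views.matrices()
        N, K = self.views.n_nodes, self.n_modules
        if init_H is not None:
            H = np.array(init_H, dtype=float)
            if H.shape != (N, K):
                raise ValueError(f"init_H must have shape {(N, K)}")
            if (H < 0).any():
                raise ValueError("init_H must be nonnegative")
        else:
            rng = np.random.default_rng(seed)
            H = rng.uniform(0.0, 1.0, size=(N, K))  # strictly positive a.s.

        # Initialization refinement: plain multi-view SNMF (S = I, no penalty).
        identity = [np.eye(K)] * len(A_list)
        for _ in range(self.warmup_iter):
            H = update_H(A_list, H, identity, 0.0, self.eps)

        def residual(A, S):
            R = A - H @ S @ H.T
            return float(np.sum(R * R))

        def safe_update_S(S_old):
            # The clipped closed form is the exact minimizer whenever clipping
            # is inactive; when clipping distorts it, keep the previous
            # (nonnegative) S so the objective never increases.
            out = []
            for v, A in enumerate(A_list):
                cand = update_S(A, H, self.eps)
                if S_old is not None and residual(A, cand) > residual(A, S_old[v]):
                    cand = S_old[v]
                out.append(cand)
            return out

        S_list = safe_update_S(None)
        trace = [objective(A_list, H, S_list, self.alpha)]
        converged = False
        iterations = 0
        # Starting from a positive H, multiplicative updates keep every entry
        # positive in exact arithmetic; the floor only guards against floating
        # underflow of redundant columns (e.g. when K exceeds the number of
        # modules the data supports), which would break column normalization.
        tiny = 1e-120

        def safe_update_H(S_list, obj_now):
            # The multiplicative ratio r is a descent direction in the step
            # exponent (each entry of log r opposes the gradient sign), so
            # halving the exponent until the objective stops increasing
            # guarantees a monotone trace; the full step is kept whenever it
            # already descends, which is the overwhelmingly common case.
            full = np.maximum(update_H(A_list, H, S_list, self.alpha, self.eps), tiny)
            cand = full
            obj_cand = objective(A_list, cand, S_list, self.alpha)
            gamma = 1.0
            while obj_cand > obj_now and gamma > 1e-4:
                gamma /= 2.0
                cand = np.maximum(H * (full / H) ** gamma, tiny)
                obj_cand = objective(A_list, cand, S_list, self.alpha)
            if obj_cand > obj_now:
                return H, obj_now
            return cand, obj_cand

        for _ in range(self.max_iter):
            S_list = safe_update_S(S_list)
            obj_after_S = objective(A_list, H, S_list, self.alpha)
            H, obj_now = safe_update_H(S_list, obj_after_S)
            trace.append(obj_now)
            iterations += 1
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) / max(prev, 1e-30) < self.tol:
                converged = True
                break
        return JSNMFResults(
            model=self,
            H=H,
            S_list=S_list,
            objective_trace=np.asarray(trace),
            iterations_run=iterations,
            converged=converged,
            seed=seed,
        )

    def fit_restarts(self, n_runs: int = 10, seed: int | None = None) -> "JSNMFRestarts":
        """Fit from ``n_runs`` random starts; see :class:`JSNMFRestarts`."""
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        seeds = np.random.SeedSequence(seed).generate_state(n_runs)
        results = [self.fit(seed=int(s)) for s in seeds]
        return JSNMFRestarts(results)


@dataclasses.dataclass
class JSNMFResults:
    """Fit results: factors, objective trajectory, and the derived partition."""

    model: JSNMF
    H: np.ndarray
    S_list: list
    objective_trace: np.ndarray
    iterations_run: int
    converged: bool
    seed: int | None = None

    def __post_init__(self):
        self._H_norm = None
        self._partition = None

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def normalized_H(self) -> np.ndarray:
        if self._H_norm is None:
            self._H_norm, self._partition = normalize_and_assign(self.H)
        return self._H_norm

    @property
    def partition(self) -> Partition:
        if self._partition is None:
            self._H_norm, self._partition = normalize_and_assign(self.H)
        return self._partition

    def max_trace_increase(self) -> float:
        """Largest one-step objective increase (<= 0 when monotone)."""
        return float(np.diff(self.objective_trace).max(initial=-np.inf))

    def summary(self) -> str:
        sizes = self.partition.sizes()
        lines = [
            "Joint symmetric NMF results",
            "===========================",
            f"views (n):        {self.model.views.n_views}",
            f"nodes (N):        {self.model.views.n_nodes}",
            f"modules (K):      {self.model.n_modules}",
            f"alpha:            {self.model.alpha:g}",
            f"iterations:       {self.iterations_run}"
            + ("" if self.converged else f" (max_iter={self.model.max_iter} reached)"),
            f"converged:        {self.converged}",
            f"final objective:  {self.final_objective:.6g}",
            f"module sizes:     {sizes.tolist()}",
        ]
        return "\n".join(lines)


class JSNMFRestarts:
    """Results of several random restarts plus representative-run selection.

    The representative run maximizes the mean adjusted Rand index to all
    other runs, i.e. it is the run most similar to the consensus of the
    ensemble.
    """

    def __init__(self, results: Sequence[JSNMFResults]):
        if not results:
            raise ValueError("no results")
        self.results = list(results)
        self._ari = None

    @property
    def n_runs(self) -> int:
        return len(self.results)

    @property
    def partitions(self) -> list:
        return [r.partition for r in self.results]

    def pairwise_ari(self) -> np.ndarray:
        if self._ari is None:
            parts = self.partitions
            m = len(parts)
            ari = np.ones((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    ari[i, j] = ari[j, i] = adjusted_rand_index(parts[i], parts[j])
            self._ari = ari
        return self._ari

    @property
    def min_pairwise_ari(self) -> float:
        """The lowest ARI among all run pairs (inter-run stability)."""
        ari = self.pairwise_ari()
        m = ari.shape[0]
        if m < 2:
            return 1.0
        off = ari[~np.eye(m, dtype=bool)]
        return float(off.min())

    @property
    def representative_index(self) -> int:
        if self.n_runs == 1:
            return 0
        return select_representative_run(self.partitions)

    @property
    def representative(self) -> JSNMFResults:
        return self.results[self.representative_index]

    @property
    def best_objective(self) -> JSNMFResults:
        return min(self.results, key=lambda r: r.final_objective)
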