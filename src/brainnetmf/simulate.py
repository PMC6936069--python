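"""Synthetic multi-view networks with a planted module structure.

The generators emulate the study design the package targets: a cohort of
subjects whose correlation networks share one modular organization, with
per-subject noise, and a labeled two-group cohort in which one group's
connectivity inside a designated module is shifted upward.  Edge weights
model correlation magnitudes directly (values in [0, 1]); no time series are
simulated.

Defaults follow the desk-scale study conditions used throughout the test
suite: 60 nodes, within-module mean weight 0.7, between-module mean 0.2,
per-view Gaussian jitter 0.05, and (for cohorts) 4 modules, 20 subjects per
group, and a +0.2 within-module shift for the positive class.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metrics import Partition
from .networks import MultiViewNetworkSet, WeightedNetwork, is_connected, preprocess_fbn

__all__ = ["PlantedConfig", "CohortConfig", "generate_multiview", "generate_cohort"]


@dataclasses.dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted-partition multi-view generator.

    p_in_mean / p_out_mean are mean edge weights within / between modules on
    the correlation scale; noise_sd is the per-view Gaussian jitter of each
    edge weight; threshold is applied post-generation through the same filter
    as real networks.
    """

    N: int = 60
    K: int = 3
    n_views: int = 5
    module_sizes: tuple | None = None
    p_in_mean: float = 0.7
    p_out_mean: float = 0.2
    noise_sd: float = 0.05
    threshold: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_out_mean < self.p_in_mean <= 1.0:
            raise ValueError("require 0 <= p_out_mean < p_in_mean <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.module_sizes is not None:
            sizes = tuple(int(s) for s in self.module_sizes)
            object.__setattr__(self, "module_sizes", sizes)
            if len(sizes) != self.K or sum(sizes) != self.N:
                raise ValueError("module_sizes must have K entries summing to N")
        if self.N < self.K or self.K < 1:
            raise ValueError("need 1 <= K <= N")

    def planted_labels(self) -> np.ndarray:
        if self.module_sizes is not None:
            sizes = self.module_sizes
        else:
            base, extra = divmod(self.N, self.K)
            sizes = tuple(base + (1 if k < extra else 0) for k in range(self.K))
        return np.repeat(np.arange(self.K), sizes)


@dataclasses.dataclass(frozen=True)
class CohortConfig(PlantedConfig):
    """Two-group cohort: positives get +effect_delta on within-module weights
    of ``effect_module``."""

    K: int = 4
    n_per_group: int = 20
    effect_module: int = 0
    effect_delta: float = 0.2

    def __post_init__(self):
        super().__post_init__()
        if not 0 <= self.effect_module < self.K:
            raise ValueError("effect_module must index one of the K modules")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be nonnegative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _mean_matrix(labels: np.ndarray, p_in: float, p_out: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    M = np.where(same, p_in, p_out).astype(float)
    np.fill_diagonal(M, 0.0)
    return M


def _draw_view(rng: np.random.Generator, M: np.ndarray, noise_sd: float,
               threshold: float, node_ids) -> WeightedNetwork:
    N = M.shape[0]
    noise = rng.normal(0.0, noise_sd, size=(N, N)) if noise_sd > 0 else np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    w = np.zeros((N, N))
    w[iu] = np.clip(M[iu] + noise[iu], 0.0, 1.0)
    w = w + w.T
    net = WeightedNetwork(node_ids, w)
    return preprocess_fbn(net, threshold)


def generate_multiview(config: PlantedConfig):
    """Draw n_views noisy realizations of one planted modular network.

    Returns ``(MultiViewNetworkSet, Partition)`` with the ground-truth
    module assignment.  Raises if the threshold disconnects every view.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.planted_labels()
    M = _mean_matrix(labels, config.p_in_mean, config.p_out_mean)
    node_ids = [str(i) for i in range(config.N)]
    views = tuple(
        _draw_view(rng, M, config.noise_sd, config.threshold, node_ids)
        for _ in range(config.n_views)
    )
    if config.threshold > 0 and not any(is_connected(v) for v in views):
        raise ValueError(
            "every generated view is disconnected at this threshold; lower it"
        )
    return MultiViewNetworkSet(views), Partition(labels, config.K)


def generate_cohort(config: CohortConfig):
    """Draw a labeled two-group cohort of subject networks.

    Negative-class subjects (label 0) follow the base planted model;
    positive-class subjects (label 1) have within-module mean weights of
    ``effect_module`` shifted by +effect_delta (clipped to [0, 1]).

    Returns ``(networks, labels, Partition)`` with negatives listed first.
    """
    rng = np.random.default_rng(config.seed)
    part_labels = config.planted_labels()
    node_ids = [str(i) for i in range(config.N)]
    M0 = _mean_matrix(part_labels, config.p_in_mean, config.p_out_mean)
    in_module = part_labels == config.effect_module
    bump = np.outer(in_module, in_module).astype(float) * config.effect_delta
    np.fill_diagonal(bump, 0.0)
    M1 = np.clip(M0 + bump, 0.0, 1.0)
    np.fill_diagonal(M1, 0.0)

    nets = [
        _draw_view(rng, M0, config.noise_sd, config.threshold, node_ids)
        for _ in range(config.n_per_group)
    ]
    nets += [
        _draw_view(rng, M1, config.noise_sd, config.threshold, node_ids)
        for _ in range(config.n_per_group)
    ]
    if config.threshold > 0 and not any(is_connected(v) for v in nets):
        raise ValueError(
            "every generated subject network is disconnected at this threshold; lower it"
        )
    labels = np.array([0] * config.n_per_group + [1] * config.n_per_group)
    return nets, labels, Partition(part_labels, config.K)
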