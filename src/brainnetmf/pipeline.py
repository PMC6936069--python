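"""End-to-end pipeline: preprocess -> cluster -> metrics -> match module ->
extract features -> classify, with every stage's outputs and a manifest
written to an artifact directory.

Clustering is fitted on the control-group (label 0) networks only by
default, because a disorder may alter the modular organization that the
clustering is meant to capture; a flag allows clustering on all subjects.
Feature extraction and classification always use all subjects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, compare_feature_scopes
from .features import match_module_to_reference
from .jsnmf import JSNMF
from .metrics import module_quality
from .networks import (
    DEFAULT_THRESHOLD,
    MultiViewNetworkSet,
    average_network,
    is_connected,
    preprocess_fbn,
    read_network,
    write_network,
)
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_cohort"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Input is either a simulated cohort (``cohort``) or explicit files
    (``network_paths`` + ``labels_path``).  The module carrying the features
    is chosen by ``reference_nodes`` (best-Jaccard match) or directly by
    ``module_index``.
    """

    outdir: str
    cohort: CohortConfig | None = None
    network_paths: list | None = None
    labels_path: str | None = None
    network_format: str = "dense"
    threshold: float = DEFAULT_THRESHOLD
    n_modules: int = 4
    alpha: float = 1.0
    runs: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    cluster_on: str = "controls"  # "controls" | "all"
    module_index: int | None = None
    reference_nodes: list | None = None
    classifiers: tuple = ("lda",)
    seed: int = 0

    def __post_init__(self):
        if (self.cohort is None) == (self.network_paths is None):
            raise ValueError("provide exactly one of cohort (simulate) or network_paths")
        if self.cluster_on not in ("controls", "all"):
            raise ValueError("cluster_on must be 'controls' or 'all'")


def load_cohort(config: RunConfig):
    """Return (networks, labels) from files or the simulator."""
    if config.cohort is not None:
        nets, labels, _truth = generate_cohort(config.cohort)
        return nets, labels
    nets = [read_network(p, format=config.network_format) for p in config.network_paths]
    labels = (
        pd.read_csv(config.labels_path, sep="\t")["label"].to_numpy(dtype=int)
        if config.labels_path
        else None
    )
    if labels is None or len(labels) != len(nets):
        raise ValueError("labels file must provide one binary label per network")
    return nets, labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("cohort",)
        },
        "stages": {},
    }
    if config.cohort is not None:
        manifest["parameters"]["cohort"] = dataclasses.asdict(config.cohort)

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = "running"

    def _done(name, **info):
        manifest["stages"][name] = "completed"
        if info:
            manifest.setdefault("stage_info", {})[name] = info

    try:
        nets, labels = load_cohort(config)

        _stage("preprocess")
        nets = [preprocess_fbn(n, config.threshold) for n in nets]
        disconnected = [i for i, n in enumerate(nets) if not is_connected(n)]
        if disconnected:
            logger.warning("%d networks disconnected after thresholding", len(disconnected))
        _done("preprocess", n_subjects=len(nets), disconnected_views=disconnected)

        _stage("cluster")
        if config.cluster_on == "controls":
            cluster_nets = [n for n, y in zip(nets, labels) if y == 0]
        else:
            cluster_nets = nets
        views = MultiViewNetworkSet(tuple(cluster_nets))
        model = JSNMF(
            views,
            n_modules=config.n_modules,
            alpha=config.alpha,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        restarts = model.fit_restarts(n_runs=config.runs, seed=config.seed)
        res = restarts.representative
        part = res.partition
        np.savetxt(out / "H.tsv", res.H, delimiter="\t", fmt="%.10g")
        for v, S in enumerate(res.S_list):
            np.savetxt(out / f"S_view{v}.tsv", S, delimiter="\t", fmt="%.10g")
        pd.DataFrame(
            {"node_id": views.node_ids, "module": part.labels}
        ).to_csv(out / "partition.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "iteration": np.arange(len(res.objective_trace)),
                "objective": res.objective_trace,
            }
        ).to_csv(out / "objective_trace.tsv", sep="\t", index=False)
        _done(
            "cluster",
            n_views=views.n_views,
            representative_run=restarts.representative_index,
            min_pairwise_ari=restarts.min_pairwise_ari,
            converged=res.converged,
        )

        _stage("metrics")
        per_view = [module_quality(v, part) for v in views.views]
        avg_q = module_quality(average_network(views), part)
        metrics_df = pd.DataFrame(
            [
                {
                    "eval_mode": "individual_mean",
                    "modularity": float(np.mean([q.modularity for q in per_view])),
                    "conductance": float(np.mean([q.conductance for q in per_view])),
                    "coverage": float(np.mean([q.coverage for q in per_view])),
                },
                {
                    "eval_mode": "average_network",
                    "modularity": avg_q.modularity,
                    "conductance": avg_q.conductance,
                    "coverage": avg_q.coverage,
                },
            ]
        )
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)
        write_network(average_network(views), out / "average_network.tsv")
        _done("metrics")

        _stage("match_module")
        if config.reference_nodes is not None:
            module_k, overlap = match_module_to_reference(
                part, config.reference_nodes, views.node_ids
            )
        elif config.module_index is not None:
            module_k, overlap = int(config.module_index), None
        else:
            raise ValueError("set module_index or reference_nodes to pick the feature module")
        (out / "module_match.json").write_text(
            json.dumps({"module": module_k, "jaccard": overlap})
        )
        _done("match_module", module=module_k, jaccard=overlap)

        _stage("extract")
        from .features import extract_features

        module_nodes = [views.node_ids[i] for i in part.module_nodes(module_k)]
        fm_module = extract_features(nets, scope=module_nodes).with_labels(labels)
        fm_whole = extract_features(nets, scope=None).with_labels(labels)
        fm_module.to_tsv(out / "features_module.tsv")
        fm_whole.to_tsv(out / "features_whole.tsv")
        _done(
            "extract",
            module_nodes=len(module_nodes),
            module_features=fm_module.n_features,
            whole_features=fm_whole.n_features,
        )

        _stage("classify")
        specs = [
            ClassifierSpec(kind, seed=config.seed + 1 + i)
            for i, kind in enumerate(config.classifiers)
        ]
        table = compare_feature_scopes(nets, labels, part, module_k, specs)
        table.to_csv(out / "auc_summary.tsv", sep="\t")
        _done("classify", auc=table.to_dict())
    except Exception as exc:
        failed = [s for s, v in manifest["stages"].items() if v == "running"]
        stage_name = failed[0] if failed else "load"
        manifest["stages"][stage_name] = f"failed: {exc}"
        (Path(config.outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
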