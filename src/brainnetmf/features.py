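"""Per-subject edge-weight feature vectors restricted to a module or the whole network.

Each subject's feature vector collects the pairwise connection weights
(Pearson correlations in real data) among a chosen node scope — one detected
module, a reference region set, or all nodes — giving m(m-1)/2 features for a
scope of m nodes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import Partition
from .networks import WeightedNetwork

__all__ = ["FeatureMatrix", "extract_features", "match_module_to_reference"]


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects x edge-weight features, with optional binary labels.

    ``feature_names`` are unordered node pairs (i, j) with i before j in the
    shared node ordering.
    """

    subjects: list
    features: np.ndarray
    feature_names: list
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(self.subjects), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match subjects/names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.subjects),):
                raise ValueError("one label per subject required")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def with_labels(self, labels) -> "FeatureMatrix":
        return FeatureMatrix(self.subjects, self.features, self.feature_names, labels)

    def to_tsv(self, path):
        cols = [f"{i}|{j}" for i, j in self.feature_names]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "subject", self.subjects)
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"subject": str})
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        subjects = df.pop("subject").tolist()
        names = [tuple(c.split("|", 1)) for c in df.columns]
        return cls(subjects, df.to_numpy(dtype=float), names, labels)


def extract_features(
    nets: Sequence[WeightedNetwork],
    scope=None,
    subjects: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Build the subjects x pairwise-weight feature matrix.

    Parameters
    ----------
    nets : sequence of WeightedNetwork
        One network per subject, sharing the node ordering.
    scope : iterable of node ids, or None
        Restrict features to pairs within these nodes; None (or "all") uses
        every node.  Scope order follows the shared node ordering; columns
        are upper-triangle pairs (i, j) with i before j.
    subjects : sequence of str, optional
        Subject identifiers; defaults to "s0", "s1", ...
    """
    nets = list(nets)
    if not nets:
        raise ValueError("no networks given")
    node_ids = nets[0].node_ids
    for net in nets[1:]:
        if net.node_ids != node_ids:
            raise ValueError("all subject networks must share one node ordering")
    if scope is None or (isinstance(scope, str) and scope.lower() == "all"):
        scope_idx = list(range(len(node_ids)))
    else:
        wanted = [str(s) for s in scope]
        missing = set(wanted) - set(node_ids)
        if missing:
            raise ValueError(f"scope nodes missing from networks: {sorted(missing)}")
        member = set(wanted)
        scope_idx = [i for i, nid in enumerate(node_ids) if nid in member]
    if len(scope_idx) < 2:
        raise ValueError("scope must contain at least 2 nodes")

    pairs = [
        (scope_idx[a], scope_idx[b])
        for a in range(len(scope_idx))
        for b in range(a + 1, len(scope_idx))
    ]
    names = [(node_ids[i], node_ids[j]) for i, j in pairs]
    rows = np.array([[net.weights[i, j] for i, j in pairs] for net in nets])
    if subjects is None:
        subjects = [f"s{i}" for i in range(len(nets))]
    return FeatureMatrix(list(subjects), rows, names)


def match_module_to_reference(p: Partition, reference_nodes, node_ids=None):
    """Find the module best matching a reference node set by Jaccard overlap.

    Returns ``(module_index, jaccard)``; ties and an everywhere-zero overlap
    resolve to the smallest module index (the latter with a warning).
    """
    import warnings

    ref = {str(r) for r in reference_nodes}
    if not ref:
        raise ValueError("reference node set is empty")
    if p.n_nodes == 0:
        raise ValueError("empty partition")
    if node_ids is None:
        node_ids = [str(i) for i in range(p.n_nodes)]
    node_ids = [str(i) for i in node_ids]
    best_k, best_j = 0, -1.0
    for k in range(p.n_modules):
        members = {node_ids[i] for i in p.module_nodes(k)}
        union = members | ref
        jac = len(members & ref) / len(union) if union else 0.0
        if jac > best_j:
            best_k, best_j = k, jac
    if best_j == 0.0:
        warnings.warn("reference set is disjoint from every module", stacklevel=2)
    return best_k, float(best_j)
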