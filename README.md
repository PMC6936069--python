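# brainnetmf

Module detection in multi-subject functional brain networks by **joint
symmetric non-negative matrix factorization**, the standard module-quality
indices, and a **module-based feature-selection strategy** for two-group
classification — e.g. asking whether connectivity features restricted to
the default mode network separate patients from controls better than
whole-brain features.

It is written for researchers working with weighted correlation networks
(functional connectivity, co-expression, any symmetric nonnegative
similarity structure) who want a reproducible pipeline from raw adjacency
matrices to a module partition and a classifier comparison, and for
methodologists who need a tested reference implementation of the joint
factorization and its evaluation conventions.

## The model

Given n symmetric nonnegative adjacency matrices A⁽ᵛ⁾ ∈ ℝ^{N×N} over one
shared node set (one "view" per subject), the factorization finds a single
nonnegative indicator matrix H ∈ ℝ^{N×K} and per-view mixing matrices
S⁽ᵛ⁾ ∈ ℝ^{K×K} minimizing

    Σᵥ ‖A⁽ᵛ⁾ − H S⁽ᵛ⁾ Hᵀ‖²_F  +  4α Σₖ ‖hₖ‖₁ ,    H ≥ 0, S⁽ᵛ⁾ ≥ 0.

Optimization alternates a closed-form least-squares solve for each S⁽ᵛ⁾
with a KKT-derived multiplicative update of H, with safeguards that make
the objective trace non-increasing by construction (see
`docs/methods.md`).  Columns of H are normalized to maximum 1 and each
node joins the module with its largest row entry.  Partition quality is
measured by weighted modularity, conductance and coverage; partition
stability across random restarts by the adjusted Rand index (ARI).
Classifiers are compared by leave-one-out ROC/AUC with explicit threshold
conventions, with recursive feature elimination and binary particle-swarm
feature selection available as leakage-safe wrappers.

The API follows the model/results idiom: construct `JSNMF(views, ...)`,
call `.fit()` or `.fit_restarts()`, and inspect the returned results
object (`H`, `S_list`, `objective_trace`, `partition`, `summary()`).

## Worked example

A simulated cohort of 20+20 subjects over 60 nodes with 4 planted modules;
the positive group's connectivity inside one module is shifted upward by
0.04.  Networks are filtered (negative weights removed, threshold 0.35),
the factorization is fitted on the control group only, the module of
interest is identified by overlap with a reference node list, and an LDA /
linear-SVM comparison is run with module-scope versus whole-network
features:

```python
from brainnetmf import (
    CohortConfig, JSNMF, MultiViewNetworkSet, ClassifierSpec,
    generate_cohort, preprocess_fbn, module_quality, average_network,
    compare_feature_scopes, match_module_to_reference,
)

cohort = CohortConfig(N=60, K=4, n_per_group=20, effect_module=0,
                      effect_delta=0.04, seed=11)
nets, labels, truth = generate_cohort(cohort)
nets = [preprocess_fbn(n, threshold=0.35) for n in nets]

controls = MultiViewNetworkSet(tuple(n for n, y in zip(nets, labels) if y == 0))
model = JSNMF(controls, n_modules=4, alpha=1.0)
restarts = model.fit_restarts(n_runs=10, seed=1)
res = restarts.representative
print(f"min pairwise ARI over 10 runs: {restarts.min_pairwise_ari:.3f}")

q = module_quality(average_network(controls), res.partition)
print(f"average network: modularity={q.modularity:.4f} "
      f"conductance={q.conductance:.4f} coverage={q.coverage:.4f}")

reference = [str(i) for i in range(15)]   # reference ROI list for the module
k, jaccard = match_module_to_reference(res.partition, reference, controls.node_ids)
print(f"module matching the reference set: {k} (Jaccard {jaccard:.2f})")

table = compare_feature_scopes(nets, labels, res.partition, k,
                               [ClassifierSpec("lda", seed=0),
                                ClassifierSpec("linear_svm", seed=0)])
print(table.round(4))
```

which prints

```
min pairwise ARI over 10 runs: 1.000
average network: modularity=0.7486 conductance=0.9986 coverage=0.9986
module matching the reference set: 2 (Jaccard 1.00)
                  lda  linear_svm
module         1.0000         1.0
whole_network  0.9138         1.0
```

Every restart found the same partition (min ARI 1.0), the detected modules
are near-perfectly assortative on the averaged control network, and the
105 module-scope features give LDA a perfect leave-one-out AUC while the
1770 whole-network features dilute the same signal (AUC 0.91) — the
module-based selection strategy in miniature.

The same pipeline is scriptable from the shell:

```sh
brainnetmf simulate --n-nodes 60 --k 4 --n-per-group 20 --seed 11 --outdir cohort/
brainnetmf run --config run.yaml        # preprocess → cluster → metrics →
                                        # match-module → extract → classify
```

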