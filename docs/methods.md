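# Methods

## Model

`brainnetmf` detects a shared modular organization in a cohort of weighted
undirected networks and evaluates whether features restricted to one
detected module discriminate two groups of subjects better than
whole-network features.  The intended data are functional brain networks
(FBNs): nodes are regions of interest (ROIs) and edge weights are Pearson
correlations of their resting-state BOLD signals, but nothing in the code
is specific to neuroimaging beyond that framing.

Given n symmetric nonnegative adjacency matrices A⁽ᵛ⁾ ∈ ℝ^{N×N} (one per
subject, "views" of one underlying organization), the joint symmetric NMF
model seeks a single nonnegative indicator matrix H ∈ ℝ^{N×K} and per-view
nonnegative mixing matrices S⁽ᵛ⁾ ∈ ℝ^{K×K} minimizing

    O(H, {S⁽ᵛ⁾}) = Σᵥ ‖A⁽ᵛ⁾ − H S⁽ᵛ⁾ Hᵀ‖²_F + 4α Σₖ ‖hₖ‖₁ ,
    H ≥ 0, S⁽ᵛ⁾ ≥ 0,

where hₖ is the k-th column of H and α ≥ 0 weights an L1 penalty that
pushes H toward a sparse, near-indicator structure.  Sharing H across views
encodes the assumption that subjects differ in individual connections but
share one module structure; S⁽ᵛ⁾ absorbs per-subject module-level
connectivity strengths.

Modules are read off H after column normalization: each column is scaled so
its maximum is 1 (balancing module sizes), and node i joins the module with
the largest normalized entry in row i (ties to the smallest index).

### Optimization

The fit alternates two steps until the relative objective change drops
below `tol` or `max_iter` is reached (one iteration = all n S-steps, then
one H-step, objective recorded after both):

* **S-step** — the unconstrained least-squares minimizer
  S⁽ᵛ⁾ = (HᵀH)⁻¹ Hᵀ A⁽ᵛ⁾ H (HᵀH)⁻¹, symmetrized and clipped at zero
  (a rank-deficient HᵀH falls back to the pseudo-inverse with a warning).
  Because clipping can move the solution away from the minimizer, the fit
  accepts the candidate per view only when it does not increase that view's
  residual at the current H; otherwise the previous (nonnegative) S is
  kept.  The guard is inactive whenever clipping is inactive, which is the
  usual case near convergence.
* **H-step** — the KKT-derived multiplicative rule
  H ← H ⊙ [Σᵥ A⁽ᵛ⁾HS⁽ᵛ⁾] ⊘ [Σᵥ HS⁽ᵛ⁾HᵀHS⁽ᵛ⁾ + αE + ε], with E the all-ones
  N×K matrix, so the sparsity penalty enters the denominator and shrinks H.
  Multiplicative rules of this quartic form are not provably monotone; since
  each entry of log(numerator/denominator) opposes the corresponding
  gradient sign, the ratio is a descent direction in the step exponent, and
  the fit backtracks (H ⊙ r^γ, γ halved) in the rare event the full step
  would increase the objective.  Together the two guards make the recorded
  objective trace non-increasing by construction, which the test suite
  verifies across random instances.

**Initialization.** H starts i.i.d. uniform(0, 1).  Before the alternating
phase, `warmup_iter` (default 100) multiplicative H-steps are run with
every S⁽ᵛ⁾ fixed at the identity and no penalty — i.e. plain multi-view
symmetric NMF.  This matters: with a free S from the first step, the
closed-form S at a random H is strongly off-diagonal, the model can fit a
merged-module solution well, and the alternating scheme reproducibly lands
in such local minima (on an exact noiseless 3-block matrix, 0 of 5 random
starts recovered the blocks; the failure persists with exact NNLS or
multiplicative S-steps, so it is a property of the free-S landscape, not of
clipping).  Warm-starting with S = I aligns the columns of H with the
data's diagonal block structure first; recovery on planted benchmarks then
succeeds in every restart.  The converged solution remains a fixed point of
the alternating updates.

**Floating-point floor.** Entries of H are floored at 1e−120 inside the
fit.  From a positive start, multiplicative updates keep H positive in
exact arithmetic; the floor only prevents redundant columns (K larger than
the data supports) from underflowing to exact zero, which would break
column normalization.  `update_H` itself preserves exact zeros, as a
multiplicative rule must.

### Defaults and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_modules` (K) | — | module count; the FBN analyses this package mirrors use K = 4 |
| `alpha` | 1.0 | L1 sparsity weight on H (dimensionless) |
| `max_iter` | 500 | iteration cap |
| `tol` | 1e−6 | relative objective change declaring convergence |
| `eps` | 1e−12 | denominator stabilizer (avoids 0/0) |
| `warmup_iter` | 100 | S = I initialization-refinement steps |
| restarts | 10 | random restarts in `fit_restarts` / `quality_scan` |

Because the factorization is randomly initialized, `fit_restarts` runs
several seeds and selects the *representative* run — the one maximizing the
mean adjusted Rand index (ARI) to all other runs; `min_pairwise_ari`
summarizes inter-run stability.  The objective-best run is also exposed.

## Network preprocessing

Raw correlation networks are filtered before clustering: negative weights
are removed first, then weights strictly below a threshold (default 0.35,
the conventional cutoff for suppressing noise-level correlations); a weight
exactly at the threshold survives.  The filter is idempotent and the
diagonal is forced to zero.  Connectivity after thresholding is reported,
not repaired: the threshold is applied globally and disconnected views are
flagged.  The average network is computed *after* per-view filtering, so
the same filtered matrices feed both per-view and average-network indices.

## Module-quality indices

With V_k (module volume) and W_k (intra-module weight), both counting each
undirected edge in both orientations, and T the total weight:

* modularity  Σₖ (W_k/T − (V_k/T)²) — weighted Newman–Girvan form; the
  normalization by T places values in their conventional range and is the
  reading consistent with reporting these indices on a (0, 1)-type scale;
* conductance (1/K′) Σₖ W_k/V_k over the K′ non-empty modules — modules
  with zero volume are excluded with a warning;
* coverage    Σₖ W_k/T.

Empty modules contribute zero to modularity and coverage.  `quality_scan`
reports all three indices over a (K, α) grid, both averaged over per-view
evaluations with the single shared partition and on the average network;
the averaged matrix is not re-thresholded.

## Feature extraction and classification

Per-subject feature vectors collect the upper-triangle edge weights among a
node scope — one module (chosen by index, or by best Jaccard overlap with a
reference ROI list) or all nodes — giving m(m−1)/2 features for m scope
nodes.  Features default to the preprocessed (nonnegative, thresholded)
networks; raw signed correlations can be supplied instead since the
networks are not forced nonnegative at construction.

Evaluation is leave-one-out cross-validation: each subject is scored by a
model trained on all others, with features z-scored inside each training
fold only.  SVM-family classifiers emit the signed margin and their ROC is
swept over the observed score range; probabilistic classifiers emit the
class-1 probability, swept over a 101-point grid on [0, 1].  Both sweeps
are bracketed by ∓∞ so the curve always contains (0,0) and (1,1).  A
subject is predicted positive iff score ≥ threshold; TPR = TP/P,
FPR = FP/N; AUC is the trapezoidal integral of TPR over FPR (sorted by
FPR, ties resolved by TPR).  On tie-free scores this equals the pairwise
rank statistic exactly.

Classifier internals (linear SVM, random forest, LDA, L1-regularized
logistic regression, kNN) are delegated to scikit-learn; unstated
hyperparameters use common defaults (SVM C = 1, RF 500 trees, kNN k = 5).
Two bespoke selection wrappers run *inside every training fold* (so the
held-out subject never informs selection; a protocol that selected once on
all data would be leakage-prone):

* **RFE** — repeatedly fit a linear SVM, rank features by |weight|, drop
  the bottom half (at least one) until `n_keep` (default 10) remain;
* **binary PSO** — swarm of binary masks, velocities with inertia decaying
  0.9 → 0.4, cognitive/social constants c1 = c2 = 2, positions resampled as
  Bernoulli(sigmoid(velocity)), fitness = internal 3-fold cross-validated
  AUC of a linear SVM; swarm 20, 30 iterations.  The all-ones mask is
  seeded as one initial particle, so the selected mask never scores below
  using all features on the internal criterion; all-zero masks are
  repaired to one random feature.

## Synthetic data

The generator draws each view's edge weight from
Normal(p_in, σ) within planted modules and Normal(p_out, σ) between them,
symmetrizes, clips to [0, 1], zeroes the diagonal, and applies the same
threshold filter as real data.  Cohorts add a positive class whose
within-module means in one designated module are shifted by +δ.  Default
conditions: N = 60 nodes, p_in = 0.7, p_out = 0.2, σ = 0.05; recovery
benchmarks use K = 3 with 5 views; cohorts use K = 4, 20 subjects per
group, δ = 0.2.  These scales keep a strong, clearly recoverable module
signal — the regime the clustering stage assumes — while running in
seconds on one CPU; they are deliberately far smaller than the 264-ROI,
~40-subject cohorts of real FBN studies.

What the generator does *not* emulate: negative correlations, spatial
autocorrelation of ROIs, heavy-tailed or heteroscedastic correlation noise,
subject-level covariates, and any time-series structure (weights model
correlation magnitudes directly).  Passing tests therefore demonstrate the
correctness of the algorithms and the internal consistency of the pipeline
under a clean planted-signal regime, not classification performance on
real imaging cohorts.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: 64 random instances
(N ∈ {10, 30}, K ∈ {2, 4}, n ∈ {1, 3}, α ∈ {0, 1}) for optimizer
monotonicity and one-step exactness; the N = 60 planted benchmark with 10
restarts for recovery and inter-run stability; 100 random 8-node instances
for the index oracles; 100 random tie-free score sets for the AUC oracle;
and 10 simulated cohorts (N = 60, K = 4, 20+20 subjects, δ = 0.2) for the
module-versus-whole-network comparison with LDA.

## Known limitations

* The objective is non-convex; different seeds can converge to different
  partitions.  Restarts plus representative-run selection mitigate but do
  not eliminate this.
* K must be supplied; the package offers a quality scan over K rather than
  automatic model selection.
* The conductance mean divides by the number of non-empty modules, which
  differs from dividing by K when modules empty out at large K.
* LOOCV AUC on small cohorts has high variance; the null distribution of
  the LOOCV rank statistic is slightly pessimistic (below 0.5 on average),
  a known property of leave-one-out protocols.
* The pipeline consumes ready-made correlation networks; computing
  correlations from time series, atlas handling, and image preprocessing
  are out of scope.
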