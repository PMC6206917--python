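# Methods

## Model and procedure

The selector is a filter method: it scores genes from the structure of the
labeled expression matrix alone, independent of any downstream classifier.
Given an n×l matrix X (samples × genes) and class labels with C ≥ 2 classes:

1. **Normalization.** Each gene is z-scored across samples,
   z = (x − μ)/σ, with the *sample* (n−1) standard deviation — the standard
   choice for small-n expression studies.  Genes with σ = 0 become all-zero
   columns and are recorded rather than rejected, since real matrices contain
   constant probes; a zero column carries no class structure and ends up at
   the uninformative end of the ranking.
2. **Class centroids.** v_ik is the gene-wise arithmetic mean of class i's
   samples, classes ordered by first appearance.
3. **Per-gene kernel dissimilarity.** The mixture kernel
   K(a,b) = c·exp(−γ₁(a−b)²) + (1−c)·exp(−γ₂(a−b)²) is applied
   *coordinate-wise* (scalar per-gene values, never whole profiles) and the
   induced squared feature-space distance 2(1 − K) is summed over all samples
   against their own class centroid:
   D_k = Σ_i Σ_{j∈C_i} 2(1 − K(x_jk, v_ik)), so 0 ≤ D_k < 2n.
   D depends only on the data and kernel, never on the weights, so it is
   computed once per run.
4. **Weight optimization.** J(w) = Σ w_k D_k + δ Σ w_k² is minimized on the
   probability simplex.  At fixed δ the Lagrangian stationary point is
   w_k = 1/l + (mean(D) − D_k)/(2δ), which sums to one algebraically;
   entries driven negative by a small δ are clipped to zero and the vector
   renormalized.  Starting from uniform w = 1/l, δ is rescaled each
   iteration before the weight update:
   - improved schedule (default, `variant="dkbcgs"`):
     δ = |Σ w_k D_k / Σ w_k²|;
   - original schedule (`variant="kbcgs"`): the same ratio times α
     (default 0.05).
   The loop stops when |J⁽ᵗ⁺¹⁾ − J⁽ᵗ⁾| < θ = 10⁻⁶ or after 100 iterations.
   The absolute value in the convergence test avoids declaring convergence on
   an objective *increase*; the ratio itself is provably nonnegative for
   D ≥ 0, so the schedule's absolute value is retained only for fidelity to
   the update's definition.

Because the update is monotone non-increasing in D_k, the final ranking
always equals ascending-D order; the iteration determines the converged
weight *magnitudes* and documents convergence through the objective trace.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| γ₁ | narrow (local) kernel bandwidth, 1/(expression units)² (unitless after z-scoring) | 1.0 | O(1) scale of z-scored data |
| γ₂ | wide (global) kernel bandwidth | 0.1 | an order of magnitude flatter, giving the heavy tail that motivates the mixture |
| c | mixture coefficient ∈ [0,1] | 0.5 | equal mixture; no fitting rule exists, so it is exposed to the grid search |
| θ | convergence tolerance on \|ΔJ\| | 10⁻⁶ | prescribed stopping rule |
| max_iter | iteration cap | 100 | prescribed cap; all tested regimes converge in < 10 |
| α | δ scale of the original schedule | 0.05 | the documented constant for that variant |

Degenerate inputs: l = 1 returns w = (1) immediately; if every weighted
dissimilarity vanishes (each sample equal to its class centroid on every
weighted gene) the δ ratio is undefined — the loop stops with a warning and
`converged=False`, returning the current weights.

## Evaluation harness

Selected subsets are judged by seeded **stratified** k-fold cross-validation
(default 10 folds; stratified because class sizes in this regime are small
and often unbalanced).  If the smallest class has fewer samples than folds,
the fold count is reduced with a warning.  Fold-wise normalization is fit on
training samples only.  Two classifier families are provided:

- `knn`: 5-nearest-neighbors, Euclidean distance on the selected genes
  (`knn-kernel` swaps in the kernel-induced dissimilarity
  √(Σ_k 2(1−K)) as a precomputed metric);
- `svm`: support-vector classifier with the same double-RBF kernel as
  selection, applied to whole profiles, unit regularization.

Selection inside cross-validation defaults to **per-fold refitting**
(weights computed on each training fold, so test samples never influence
which genes are chosen); a `global` mode reuses one full-data ranking for
every fold, which is optimistic but provided for comparability with
protocols that rank once up front.

Metrics are the confusion-count identities ACC = (TP+TN)/total,
TPR = TP/(TP+FN), TNR = TN/(FP+TN), with the lexicographically second label
as the positive class unless overridden; for multiclass problems TPR/TNR are
macro-averages of per-class recall/specificity (stated in the report
header).  ROC points sweep the unique classifier scores and AUC uses the
trapezoid rule.  The gene-count sweep covers k = 1..50 by default, reporting
mean error 1 − ACC per k and the smallest k attaining the minimum.  The
hyperparameter grid search is full-factorial over (γ₁, γ₂, c), scored by the
best accuracy over the k sweep, first-in-iteration-order tie-breaking.

## Synthetic data

The generator emulates the microarray benchmark regime (small n, large l,
2–5 classes): gene baselines b_g ~ N(0, baseline_sd²); a seeded random
subset of `n_informative` genes receives class shifts
effect_size·noise_sd·s_i with class scores s_i equally spaced in [−1, 1]
(so multiclass structure is ordered and symmetric); observations add
N(0, noise_sd²) noise.  Defaults — 20 informative genes, effect size 2,
unit noise — give a clearly separable but not trivial two-class gap of
4 noise-SD between extreme classes.  Shape presets mirror the benchmark
datasets (77/2/7129, 40/2/1519, 152/5/65522, 62/3/4026 as
samples/classes/genes).

Not modeled, deliberately: gene–gene covariance, batch effects, heavy tails,
count (sequencing) noise.  Passing recovery tests therefore demonstrates
the machinery is correct under the stated generative model, not performance
on real tumor data.

## Numerical choices

- Weight ties (identical D) are broken by gene index ascending, everywhere
  ranking appears — the tables, `rank_and_select`, `GeneWeights.order`.
- Exponential underflow saturates the kernel distance at exactly 2; this is
  accepted (no clamping), it simply means two values are maximally far.
- The clip-and-renormalize projection equals the exact simplex-constrained
  minimizer whenever no clipping occurs; at the δ scale the schedule
  realizes (δ ≥ ΣD on the first iteration) raw weights are provably
  nonnegative for small l and empirically so in all tested regimes.
- Weight tables print 17 significant digits so a write/read round trip is
  bit-exact; all randomness flows from explicit integer seeds
  (`numpy.random.default_rng`), and fold assignment is seeded, so fixed
  (data, config, seed) reproduce outputs byte-identically.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run on the 40×1519 two-class
regime (ten seeds) plus smaller fixtures, and exercise the optimizer once on
each shape preset including 152×65522; these sizes fully exercise every code
path while keeping a complete run of suite + script under a few minutes on
one CPU.

## Known limitations

- The per-gene kernel distance ignores gene–gene interactions by
  construction: a gene pair that is only jointly informative will not be
  ranked highly.
- With many genes, first-iteration weights deviate from uniform by O(1/l)
  relative amounts; rankings are stable but weight magnitudes are close to
  uniform, so downstream consumers should use ranks, not raw weight gaps.
- The grid search refits selection per hyperparameter triple on the full
  dataset (global mode) for tractability; nest it inside an outer CV loop if
  unbiased hyperparameter selection is required.
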