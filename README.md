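# dkbcgs

Filter-style gene selection for cancer classification from expression data,
using a **double RBF-kernel** (a convex mixture of two Gaussian kernels with
different bandwidths) inside a weighted clustering objective.  The package
provides the selection algorithm (both the double-kernel variant and the
original single-kernel one), an evaluation harness (stratified
cross-validation with KNN/SVM, ACC/TPR/TNR/ROC, gene-count sweeps, kernel
grid search), a command-line interface, and a seeded synthetic-data generator
with known informative-gene ground truth.

It is aimed at the classic transcriptomics regime — tens of samples, thousands
of genes, 2–5 phenotype classes — where ranking genes *before* any classifier
is fitted keeps computation cheap and limits overfitting.

## Method

Expression values are z-scored per gene.  For each gene *k*, samples are
compared to their class centroid *v<sub>ik</sub>* in the feature space of the
mixture kernel

&nbsp;&nbsp;&nbsp;&nbsp;K(a, b) = c·e<sup>−γ₁(a−b)²</sup> + (1−c)·e<sup>−γ₂(a−b)²</sup>,

whose induced squared distance is ‖Φ(a) − Φ(b)‖² = 2(1 − K(a, b)).  Summing
over all samples gives a per-gene dissimilarity

&nbsp;&nbsp;&nbsp;&nbsp;D<sub>k</sub> = Σ<sub>i</sub> Σ<sub>j∈C<sub>i</sub></sub> 2(1 − K(x<sub>jk</sub>, v<sub>ik</sub>)),

and gene weights w on the probability simplex minimize

&nbsp;&nbsp;&nbsp;&nbsp;J(w) = Σ<sub>k</sub> w<sub>k</sub> D<sub>k</sub> + δ Σ<sub>k</sub> w<sub>k</sub>²,&nbsp;&nbsp; Σ w<sub>k</sub> = 1, w<sub>k</sub> ∈ [0, 1],

via the closed-form Lagrangian update
w<sub>k</sub> = 1/l + (mean(D) − D<sub>k</sub>)/(2δ), with δ rescaled each
iteration as |Σ w<sub>k</sub> D<sub>k</sub> / Σ w<sub>k</sub>²| (the improved
schedule; the original variant multiplies this ratio by a constant α = 0.05).
Iteration stops when |ΔJ| < 10⁻⁶ or after 100 rounds.  Genes with small
within-class spread relative to their overall variance get small
D<sub>k</sub> and large weights; ranking by weight gives the selected panel.

## Worked example

```python
from dkbcgs import preset, generate, run, rank_and_select, cross_validate

# benchmark-shaped synthetic data: 40 samples, 1519 genes, 2 classes,
# 10 planted informative genes with a 2-sigma class shift
ds, info = generate(preset("gastric-like", n_informative=10, seed=7))

weights, state = run(ds)          # double-kernel selection, default kernel
print("converged:", state.converged, "iterations:", state.t)

top = rank_and_select(weights, 10)
print("planted genes recovered:", len(set(top) & set(info)), "/ 10")

rep = cross_validate(ds, top, "knn", folds=10, seed=7)
print(f"ACC={rep.acc:.4f}  TPR={rep.tpr:.4f}  TNR={rep.tnr:.4f}  AUC={rep.auc:.4f}")
```

prints

```
converged: True iterations: 5
planted genes recovered: 10 / 10
ACC=1.0000  TPR=1.0000  TNR=1.0000  AUC=1.0000
```

i.e. the optimizer converged in 5 iterations, its top-10 ranking is exactly
the planted informative set, and stratified 10-fold cross-validation with a
5-nearest-neighbors classifier on those genes classifies every sample
correctly (this regime is strongly separable by construction).

The same pipeline is available from the shell:

```sh
dkbcgs simulate --preset gastric-like --n-informative 10 --seed 7 --out sim/
dkbcgs select   --matrix sim/matrix.tsv --labels sim/labels.tsv --out sel/
dkbcgs evaluate --matrix sim/matrix.tsv --labels sim/labels.tsv \
                --weights sel/weights.tsv --k 10 --out eval/
dkbcgs sweep    --matrix sim/matrix.tsv --labels sim/labels.tsv \
                --weights sel/weights.tsv --k-min 1 --k-max 50 --out sweep/
```

All outputs are TSV plus a flat `key = value` config file that reproduces the
run byte-identically when fed back in.

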