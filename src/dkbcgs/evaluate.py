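"""Gene-subset evaluation: stratified cross-validation, ACC/TPR/TNR, ROC, sweeps.

Selected gene subsets are judged by stratified k-fold cross-validation with
either a nearest-neighbors classifier (default: 5 neighbors, Euclidean
distance on the selected genes; a kernel-induced-distance mode is available)
or a maximum-margin classifier using the same double-RBF kernel as selection.

Two selection protocols are supported (the choice matters for small n):

* ``per-fold`` (default): gene weights are refit on each training fold, so
  the test fold never influences which genes are selected — the statistically
  sound protocol.
* ``global``: one weight vector fit on the full dataset is reused in every
  fold.  Optimistic, provided for comparability with protocols that rank
  genes once up front.

Metrics follow the standard confusion-matrix identities
ACC = (TP+TN)/(TP+FP+TN+FN), TPR = TP/(TP+FN), TNR = TN/(FP+TN); for
multiclass problems TPR is the macro-average of per-class recalls and TNR the
macro-average of per-class specificities.  The positive class of a two-class
problem is the lexicographically second label unless overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import core
from .data_io import ExpressionDataset
from .kernels import KernelParams, double_rbf_gram, kernel_sq_distance

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "SweepResult",
    "rank_and_select",
    "metrics_from_confusion",
    "cross_validate",
    "evaluate_selection",
    "roc",
    "sweep_k",
    "grid_search",
]

DEFAULT_FOLDS = 10
DEFAULT_KNN_NEIGHBORS = 5
DEFAULT_SVM_C = 1.0
DEFAULT_K_RANGE = range(1, 51)


@dataclass
class EvalReport:
    """Cross-validated evaluation of one gene subset."""

    confusion: np.ndarray  # C x C, rows = true, cols = predicted
    labels_order: list  # label order of the confusion axes (sorted)
    acc: float
    tpr: float
    tnr: float
    per_fold: list = field(default_factory=list)
    roc_points: list | None = None
    auc: float | None = None
    k: int = 0
    classifier_tag: str = ""
    seed: int = 0
    positive_label: object = None
    folds_used: int = 0
    selection_mode: str = "fixed"

    def to_text(self) -> str:
        """Flat key-value block for the report file."""
        lines = [
            f"classifier = {self.classifier_tag}",
            f"k = {self.k}",
            f"folds = {self.folds_used}",
            f"seed = {self.seed}",
            f"selection = {self.selection_mode}",
            f"classes = {','.join(str(c) for c in self.labels_order)}",
            f"positive_label = {self.positive_label}",
            "tpr_tnr_definition = macro-average over classes"
            if len(self.labels_order) > 2
            else "tpr_tnr_definition = two-class",
            f"acc = {self.acc:.6f}",
            f"tpr = {self.tpr:.6f}",
            f"tnr = {self.tnr:.6f}",
        ]
        if self.auc is not None:
            lines.append(f"auc = {self.auc:.6f}")
        flat = ";".join(
            ",".join(str(int(v)) for v in row) for row in self.confusion
        )
        lines.append(f"confusion = {flat}")
        return "\n".join(lines) + "\n"


@dataclass
class SweepResult:
    """Mean CV error rate as a function of the number of selected genes."""

    k_values: list[int]
    mean_error: list[float]
    best_k: int
    grid: object = None  # optional hyperparameter score table


def rank_and_select(weights, k: int) -> np.ndarray:
    """Indices of the k highest-weight genes (ties by gene index ascending)."""
    w = np.asarray(getattr(weights, "w", weights), dtype=float)
    if not (1 <= k <= w.size):
        raise ValueError(f"k must be in [1, {w.size}], got {k}")
    order = getattr(weights, "order", None)
    if order is None:
        order = np.lexsort((np.arange(w.size), -w))
    return np.asarray(order[:k])


def metrics_from_confusion(
    confusion: np.ndarray, labels_order, positive=None
) -> tuple[float, float, float]:
    """ACC, TPR, TNR from a confusion matrix (rows true, cols predicted).

    Two-class: TPR = TP/(TP+FN), TNR = TN/(FP+TN) with the given positive
    class (default: second label in ``labels_order``).  Multiclass: macro
    recall and macro specificity.
    """
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    acc = float(np.trace(cm) / total)
    C = cm.shape[0]
    if C == 2:
        pos = labels_order[1] if positive is None else positive
        p = list(labels_order).index(pos)
        n = 1 - p
        tp, fn = cm[p, p], cm[p, n]
        tn, fp = cm[n, n], cm[n, p]
        tpr = float(tp / (tp + fn)) if tp + fn else 0.0
        tnr = float(tn / (fp + tn)) if fp + tn else 0.0
    else:
        recalls, specs = [], []
        for i in range(C):
            row = cm[i].sum()
            col = cm[:, i].sum()
            tp = cm[i, i]
            tn = total - row - col + tp
            fp = col - tp
            recalls.append(tp / row if row else 0.0)
            specs.append(tn / (tn + fp) if tn + fp else 0.0)
        tpr = float(np.mean(recalls))
        tnr = float(np.mean(specs))
    return acc, tpr, tnr


def roc(scores, labels, positive=None) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoid AUC for two-class scores.

    Thresholds sweep the unique score values; points run from (0, 0) to
    (1, 1) with nondecreasing false-positive rate.
    """
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"ROC needs exactly 2 classes, got {len(uniq)}")
    pos = uniq[1] if positive is None else positive
    fpr, tpr, _ = skm.roc_curve(labels, np.asarray(scores, float), pos_label=pos)
    auc = float(skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# classifiers and the CV engine


def _make_classifier(spec: str, kernel_params: KernelParams | None, n_train: int):
    if spec == "knn":
        return KNeighborsClassifier(
            n_neighbors=min(DEFAULT_KNN_NEIGHBORS, n_train)
        )
    if spec == "knn-kernel":
        return KNeighborsClassifier(
            n_neighbors=min(DEFAULT_KNN_NEIGHBORS, n_train), metric="precomputed"
        )
    if spec == "svm":
        p = kernel_params or KernelParams()
        return SVC(C=DEFAULT_SVM_C, kernel=lambda A, B: double_rbf_gram(A, B, p))
    raise ValueError(f"unknown classifier {spec!r} (use 'knn', 'knn-kernel' or 'svm')")


def _kernel_distance_matrix(A, B, params: KernelParams) -> np.ndarray:
    """sqrt of the summed per-gene kernel distances, a metric-like dissimilarity."""
    out = np.zeros((A.shape[0], B.shape[0]))
    for k in range(A.shape[1]):
        out += kernel_sq_distance(A[:, k][:, None], B[:, k][None, :], params)
    return np.sqrt(out)


def _fold_normalize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)
    tr = (train - mu) / safe
    te = (test - mu) / safe
    zero = sd == 0
    tr[:, zero] = 0.0
    te[:, zero] = 0.0
    return tr, te


def _stratified_splits(labels: np.ndarray, folds: int, seed: int):
    """Seeded stratified folds; every class must survive in each training set."""
    _, counts = np.unique(labels, return_counts=True)
    eff = min(folds, int(counts.min()))
    if eff < folds:
        warnings.warn(
            f"reducing folds from {folds} to {eff}: smallest class has "
            f"{counts.min()} samples",
            stacklevel=3,
        )
    if eff < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(labels.size), labels))
        if all(
            set(np.unique(labels[tr])) == set(np.unique(labels)) for tr, _ in splits
        ):
            return splits, eff
    raise ValueError("could not build folds with every class in each training set")


def _cv_engine(
    ds: ExpressionDataset,
    classifier_spec: str,
    folds: int,
    seed: int,
    kernel_params: KernelParams | None,
    subset=None,
    select: dict | None = None,
    positive=None,
) -> EvalReport:
    labels = ds.labels
    labels_order = sorted(set(labels.tolist()))
    two_class = len(labels_order) == 2
    pos = (labels_order[1] if positive is None else positive) if two_class else None

    splits, eff = _stratified_splits(labels, folds, seed)
    C = len(labels_order)
    pooled = np.zeros((C, C), dtype=int)
    per_fold = []
    all_scores, all_true = [], []

    for fold_i, (tr_idx, te_idx) in enumerate(splits):
        if select is not None:
            train_ds = ds.subset_samples(tr_idx)
            gw, _ = core.run(
                train_ds,
                select["params"],
                variant=select.get("variant", "dkbcgs"),
                theta=select.get("theta", core.DEFAULT_THETA),
                max_iter=select.get("max_iter", core.DEFAULT_MAX_ITER),
                alpha=select.get("alpha", core.DEFAULT_ALPHA),
            )
            fold_subset = rank_and_select(gw, select["k"])
        else:
            fold_subset = np.asarray(subset)
            if fold_subset.size == 0:
                raise ValueError("gene subset must be nonempty")

        Xtr, Xte = _fold_normalize(
            ds.values[np.ix_(tr_idx, fold_subset)],
            ds.values[np.ix_(te_idx, fold_subset)],
        )
        ytr, yte = labels[tr_idx], labels[te_idx]

        clf = _make_classifier(classifier_spec, kernel_params, len(tr_idx))
        if classifier_spec == "knn-kernel":
            p = kernel_params or KernelParams()
            clf.fit(_kernel_distance_matrix(Xtr, Xtr, p), ytr)
            Xpred = _kernel_distance_matrix(Xte, Xtr, p)
        else:
            clf.fit(Xtr, ytr)
            Xpred = Xte
        ypred = clf.predict(Xpred)

        cm = skm.confusion_matrix(yte, ypred, labels=labels_order)
        pooled += cm
        per_fold.append(
            {
                "fold": fold_i,
                "confusion": cm,
                "selected": np.sort(fold_subset).tolist(),
                "test_samples": np.asarray(te_idx).tolist(),
            }
        )

        if two_class:
            if hasattr(clf, "decision_function"):
                sc = clf.decision_function(Xpred)
                if list(clf.classes_)[1] != pos:  # flip so larger = positive
                    sc = -sc
            else:
                proba = clf.predict_proba(Xpred)
                sc = proba[:, list(clf.classes_).index(pos)]
            all_scores.append(np.asarray(sc, float))
            all_true.append(yte)

    acc, tpr, tnr = metrics_from_confusion(pooled, labels_order, positive=pos)
    roc_points = auc = None
    if two_class:
        scores = np.concatenate(all_scores)
        true = np.concatenate(all_true)
        roc_points, auc = roc(scores, true, positive=pos)

    k_used = int(select["k"]) if select is not None else int(np.asarray(subset).size)
    return EvalReport(
        confusion=pooled,
        labels_order=labels_order,
        acc=acc,
        tpr=tpr,
        tnr=tnr,
        per_fold=per_fold,
        roc_points=roc_points,
        auc=auc,
        k=k_used,
        classifier_tag=classifier_spec,
        seed=seed,
        positive_label=pos,
        folds_used=eff,
        selection_mode="per-fold" if select is not None else "fixed",
    )


def cross_validate(
    ds: ExpressionDataset,
    subset,
    classifier_spec: str = "knn",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    kernel_params: KernelParams | None = None,
    positive=None,
) -> EvalReport:
    """Stratified CV of a fixed gene subset (indices into ``ds.gene_ids``)."""
    return _cv_engine(
        ds, classifier_spec, folds, seed, kernel_params, subset=subset, positive=positive
    )


def evaluate_selection(
    ds: ExpressionDataset,
    k: int,
    kernel_params: KernelParams | None = None,
    classifier_spec: str = "knn",
    variant: str = "dkbcgs",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    selection: str = "per-fold",
    positive=None,
    **optimizer_kwargs,
) -> EvalReport:
    """Run selection + CV end to end, refitting weights per fold by default."""
    params = kernel_params or KernelParams()
    if selection == "per-fold":
        select = {"params": params, "k": k, "variant": variant, **optimizer_kwargs}
        return _cv_engine(
            ds, classifier_spec, folds, seed, params, select=select, positive=positive
        )
    if selection == "global":
        gw, _ = core.run(ds, params, variant=variant, **optimizer_kwargs)
        report = _cv_engine(
            ds,
            classifier_spec,
            folds,
            seed,
            params,
            subset=rank_and_select(gw, k),
            positive=positive,
        )
        report.selection_mode = "global"
        return report
    raise ValueError(f"selection must be 'per-fold' or 'global', got {selection!r}")


def sweep_k(
    ds: ExpressionDataset,
    weights,
    classifier_spec: str = "knn",
    k_range=DEFAULT_K_RANGE,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    kernel_params: KernelParams | None = None,
) -> SweepResult:
    """Mean CV error rate for each top-k subset of a fixed gene ranking.

    ``best_k`` is the smallest k attaining the minimum error.
    """
    k_values = [int(k) for k in k_range]
    if not k_values:
        raise ValueError("k_range must be nonempty")
    errors = []
    for k in k_values:
        rep = cross_validate(
            ds,
            rank_and_select(weights, k),
            classifier_spec,
            folds=folds,
            seed=seed,
            kernel_params=kernel_params,
        )
        errors.append(1.0 - rep.acc)
    best_k = k_values[int(np.argmin(errors))]
    return SweepResult(k_values=k_values, mean_error=errors, best_k=best_k)


def grid_search(
    ds: ExpressionDataset,
    gamma1_grid,
    gamma2_grid,
    c_grid,
    classifier_spec: str = "knn",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    k_range=DEFAULT_K_RANGE,
    variant: str = "dkbcgs",
) -> tuple[KernelParams, list[dict]]:
    """Full-factorial search over (gamma1, gamma2, c).

    Each triple is scored by its best mean CV accuracy over the k sweep;
    ties keep the first triple in iteration order (gamma1 outer, gamma2
    middle, c inner).  Returns the winning parameters and the full table.
    """
    g1s, g2s, cs = list(gamma1_grid), list(gamma2_grid), list(c_grid)
    if not (g1s and g2s and cs):
        raise ValueError("all grids must be nonempty")
    best, best_score = None, -np.inf
    table = []
    for g1 in g1s:
        for g2 in g2s:
            for c in cs:
                params = KernelParams(gamma1=g1, gamma2=g2, c=c)
                gw, _ = core.run(ds, params, variant=variant)
                sweep = sweep_k(
                    ds,
                    gw,
                    classifier_spec,
                    k_range=k_range,
                    folds=folds,
                    seed=seed,
                    kernel_params=params,
                )
                score = 1.0 - min(sweep.mean_error)
                table.append(
                    {
                        "gamma1": g1,
                        "gamma2": g2,
                        "c": c,
                        "best_k": sweep.best_k,
                        "accuracy": score,
                    }
                )
                if score > best_score:
                    best, best_score = params, score
    logger.info("grid search best: %s (accuracy %.4f)", best, best_score)
    return best, table
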