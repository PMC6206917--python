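"""Weighted kernel clustering optimizer for gene selection.

The method scores each gene by how tightly samples cluster around their class
centroid *for that gene alone*, measured in the feature space of a (double)
RBF kernel, and converts those per-gene dissimilarities into a
simplex-constrained weight vector by minimizing

    J(w) = sum_k w_k D_k + delta * sum_k w_k^2,
    subject to  w_k in [0, 1],  sum_k w_k = 1,

where D_k aggregates the kernel-induced squared distance between each sample
and its class centroid on gene k.  The first term alone would put all mass on
the single most discriminative gene; the quadratic penalty alone prefers
uniform weights; delta balances the two.  Minimizing the Lagrangian gives the
closed-form update

    w_k = 1/l + (1 / (2 delta)) * (mean(D) - D_k),

which sums to one algebraically.  delta is rescaled each iteration so both
terms stay on the same order of magnitude:

    delta = | sum_k w_k D_k / sum_k w_k^2 |           (default schedule)
    delta = alpha * sum_k w_k D_k / sum_k w_k^2       (original schedule)

The two schedules are selected by ``variant`` ("dkbcgs" — the improved
absolute-ratio schedule — or "kbcgs", the original alpha-scaled one).  With
``alpha = 1`` they coincide, since the ratio is nonnegative for D >= 0.

Because D does not depend on w, the weight ordering is fully determined by D
(weights are non-increasing in D_k), but the iteration is still needed to find
the converged magnitude of the weights, and the objective trace documents
convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset, zscore_normalize
from .kernels import KernelParams, double_rbf_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterCenters",
    "GeneWeights",
    "OptimizerState",
    "compute_centers",
    "per_gene_dissimilarity",
    "update_weights",
    "update_delta_dkbcgs",
    "update_delta_kbcgs",
    "objective",
    "run",
]

#: convergence tolerance on |J(t+1) - J(t)|
DEFAULT_THETA = 1e-6
#: iteration cap
DEFAULT_MAX_ITER = 100
#: delta scale constant of the original (kbcgs) schedule
DEFAULT_ALPHA = 0.05


@dataclass
class ClusterCenters:
    """Per-class, per-gene centroids of the (normalized) expression matrix."""

    centers: np.ndarray  # C x l
    class_order: list  # first-appearance order of labels
    class_sizes: list[int]


@dataclass
class GeneWeights:
    """Simplex-constrained gene weights with their ranking order.

    ``order`` lists gene indices best-first (descending weight, ties broken
    by gene index ascending); ``ranks`` maps gene index -> 1-based rank.
    """

    w: np.ndarray
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.order = np.lexsort((np.arange(self.w.size), -self.w))

    @property
    def ranks(self) -> np.ndarray:
        r = np.empty(self.w.size, dtype=int)
        r[self.order] = np.arange(1, self.w.size + 1)
        return r


@dataclass
class OptimizerState:
    t: int = 0
    delta: float = 0.0
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    theta: float = DEFAULT_THETA
    max_iter: int = DEFAULT_MAX_ITER
    alpha: float = DEFAULT_ALPHA


def _as_w(w) -> np.ndarray:
    return np.asarray(getattr(w, "w", w), dtype=float)


def compute_centers(ds: ExpressionDataset) -> ClusterCenters:
    """Gene-wise arithmetic mean of each class's samples.

    Class order is the first-appearance order of labels in the dataset.
    """
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes, got {len(classes)}")
    centers = np.empty((len(classes), ds.l))
    sizes = []
    for i, lab in enumerate(classes):
        idx = ds.labels == lab
        if not idx.any():
            raise ValueError(f"class {lab!r} has no samples")
        centers[i] = ds.values[idx].mean(axis=0)
        sizes.append(int(idx.sum()))
    return ClusterCenters(centers=centers, class_order=classes, class_sizes=sizes)


def per_gene_dissimilarity(
    ds: ExpressionDataset, centers: ClusterCenters, params: KernelParams
) -> np.ndarray:
    """Per-gene kernel dissimilarity D_k between samples and class centroids.

    D_k = sum over classes i, samples j in class i of
    ||Phi(x_jk) - Phi(v_ik)||^2 = 2 (1 - K(x_jk, v_ik)), so 0 <= D_k < 2 n.
    Informative genes — tight within-class spread after z-scoring — get small
    D_k and hence large weights.
    """
    if centers.centers.shape != (len(centers.class_order), ds.l):
        raise ValueError(
            f"centers shape {centers.centers.shape} does not match "
            f"{len(centers.class_order)} classes x {ds.l} genes"
        )
    D = np.zeros(ds.l)
    for i, lab in enumerate(centers.class_order):
        idx = ds.labels == lab
        sq = (ds.values[idx] - centers.centers[i]) ** 2
        D += (2.0 * (1.0 - double_rbf_kernel(sq, params))).sum(axis=0)
    return D


def update_weights(D: np.ndarray, delta: float) -> GeneWeights:
    """Closed-form minimizer of J at fixed delta, projected onto the simplex.

    The raw update ``1/l + (mean(D) - D_k) / (2 delta)`` sums to one exactly;
    entries driven negative by a small delta are clipped to zero and the
    vector renormalized.  The update is non-increasing in D_k, so ranking by
    weight equals ranking by ascending dissimilarity.
    """
    if not (delta > 0):
        raise ValueError(f"delta must be > 0, got {delta}")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dissimilarities must be nonnegative")
    l = D.size
    raw = 1.0 / l + (D.mean() - D) / (2.0 * delta)
    w = np.maximum(raw, 0.0)
    s = w.sum()
    # the minimum-D gene's raw weight is >= 1/l, so s > 0 for any delta > 0
    assert s > 0, "all weights clipped to zero"
    return GeneWeights(w / s)


def _delta_ratio(D: np.ndarray, w: np.ndarray) -> float:
    num = float(w @ D)
    den = float(w @ w)
    if num == 0.0:
        raise ValueError(
            "all weighted dissimilarities vanish; data is perfectly "
            "class-separated per gene"
        )
    return num / den


def update_delta_dkbcgs(D, w_prev) -> float:
    """Improved schedule: delta = | sum w_k D_k / sum w_k^2 |."""
    return abs(_delta_ratio(np.asarray(D, dtype=float), _as_w(w_prev)))


def update_delta_kbcgs(D, w_prev, alpha: float = DEFAULT_ALPHA) -> float:
    """Original schedule: delta = alpha * sum w_k D_k / sum w_k^2."""
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return alpha * _delta_ratio(np.asarray(D, dtype=float), _as_w(w_prev))


def objective(D, w, delta: float) -> float:
    """J(w) = sum w_k D_k + delta sum w_k^2 (>= delta/l on the simplex)."""
    w = _as_w(w)
    D = np.asarray(D, dtype=float)
    return float(w @ D + delta * (w @ w))


def run(
    ds: ExpressionDataset,
    params: KernelParams | None = None,
    variant: str = "dkbcgs",
    theta: float = DEFAULT_THETA,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[GeneWeights, OptimizerState]:
    """Run the full selection pipeline on a raw dataset.

    Steps: z-score normalize, compute class centroids, compute the per-gene
    kernel dissimilarities once (they do not depend on w), then iterate the
    delta schedule and weight update from the uniform start w = 1/l until the
    objective changes by less than ``theta`` or ``max_iter`` is reached.

    Returns the final weights and an :class:`OptimizerState` carrying the
    objective trace and convergence flag.
    """
    if variant not in ("dkbcgs", "kbcgs"):
        raise ValueError(f"variant must be 'dkbcgs' or 'kbcgs', got {variant!r}")
    if params is None:
        params = KernelParams()
    state = OptimizerState(theta=theta, max_iter=max_iter, alpha=alpha)

    norm, _ = zscore_normalize(ds)
    centers = compute_centers(norm)
    D = per_gene_dissimilarity(norm, centers, params)
    l = D.size

    if l == 1:
        state.converged = True
        return GeneWeights(np.array([1.0])), state

    w = np.full(l, 1.0 / l)
    for t in range(1, max_iter + 1):
        state.t = t
        try:
            if variant == "dkbcgs":
                delta = update_delta_dkbcgs(D, w)
            else:
                delta = update_delta_kbcgs(D, w, alpha)
        except ValueError as err:
            logger.warning("degenerate delta at iteration %d: %s", t, err)
            break
        gw = update_weights(D, delta)
        w = gw.w
        state.delta = delta
        state.objective_trace.append(objective(D, w, delta))
        if (
            len(state.objective_trace) >= 2
            and abs(state.objective_trace[-1] - state.objective_trace[-2]) < theta
        ):
            state.converged = True
            break

    return GeneWeights(w), state
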