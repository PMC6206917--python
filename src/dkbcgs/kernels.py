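"""RBF and double-RBF (mixture) kernels and the kernel-induced squared distance.

The gene-selection method measures how far a sample's expression value for a
single gene lies from its class centroid, not in the raw input space but in
the feature space induced by a Gaussian kernel.  A convex combination of two
RBF kernels with different bandwidths,

    K(a, b) = c * exp(-gamma1 * (a - b)^2) + (1 - c) * exp(-gamma2 * (a - b)^2),

has a heavier tail than a single RBF: the narrow component (large gamma)
resolves local structure while the wide component (small gamma) keeps distant
points from saturating, which makes the induced dissimilarity less sensitive
to outliers.

All kernels here operate on *scalar* per-gene values: the method applies the
kernel coordinate-wise and sums the induced distances over genes.  The API
takes the already-squared difference ``sq_dist = (a - b)**2`` so callers can
never accidentally pass an unsquared distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "rbf_kernel",
    "double_rbf_kernel",
    "kernel_sq_distance",
    "double_rbf_gram",
]


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the two-RBF mixture kernel.

    Attributes
    ----------
    gamma1, gamma2
        Bandwidths of the two Gaussian components; both must be positive.
        Conventionally ``gamma1`` is the narrower (local) component.
    c
        Mixture coefficient in [0, 1].  ``c = 1`` (or ``gamma1 == gamma2``)
        degenerates to a single RBF kernel with bandwidth ``gamma1``.
    """

    gamma1: float = 1.0
    gamma2: float = 0.1
    c: float = 0.5

    def __post_init__(self) -> None:
        if not (self.gamma1 > 0):
            raise ValueError(f"gamma1 must be > 0, got {self.gamma1}")
        if not (self.gamma2 > 0):
            raise ValueError(f"gamma2 must be > 0, got {self.gamma2}")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError(f"c must be in [0, 1], got {self.c}")


def _check_sq_dist(sq_dist):
    sq = np.asarray(sq_dist, dtype=float)
    if np.any(sq < 0):
        raise ValueError("sq_dist must be nonnegative (pass squared distances)")
    return sq


def rbf_kernel(sq_dist, gamma: float):
    """Gaussian kernel ``exp(-gamma * sq_dist)`` on a squared distance.

    Returns a value in (0, 1]; equals 1 iff ``sq_dist == 0`` and is strictly
    decreasing in ``sq_dist``.  Accepts scalars or arrays.
    """
    if not (gamma > 0):
        raise ValueError(f"gamma must be > 0, got {gamma}")
    sq = _check_sq_dist(sq_dist)
    out = np.exp(-gamma * sq)
    return out if out.ndim else float(out)


def double_rbf_kernel(sq_dist, params: KernelParams):
    """Two-RBF mixture kernel ``c*exp(-g1*d) + (1-c)*exp(-g2*d)``.

    Because the mixture weights sum to one, the kernel is normalized:
    K(a, a) = 1 exactly, and the value lies in (0, 1] for finite inputs.
    """
    if not isinstance(params, KernelParams):
        params = KernelParams(*params)
    sq = _check_sq_dist(sq_dist)
    out = params.c * np.exp(-params.gamma1 * sq) + (1.0 - params.c) * np.exp(
        -params.gamma2 * sq
    )
    return out if out.ndim else float(out)


def kernel_sq_distance(a, b, params: KernelParams):
    """Squared distance between Phi(a) and Phi(b) in the kernel feature space.

    By the kernel trick, ||Phi(a) - Phi(b)||^2 = K(a,a) - 2 K(a,b) + K(b,b),
    which for any normalized kernel (K(x,x) = 1) simplifies to 2 (1 - K(a,b)).
    Symmetric in (a, b), zero iff a == b, and strictly below 2 for finite
    inputs (the kernel is positive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = 2.0 * (1.0 - double_rbf_kernel((a - b) ** 2, params))
    return out if np.ndim(out) else float(out)


def double_rbf_gram(X, Y, params: KernelParams) -> np.ndarray:
    """Gram matrix of the mixture kernel on whole expression profiles.

    Used by the maximum-margin classifier: entry (i, j) is
    ``c*exp(-g1*||X_i - Y_j||^2) + (1-c)*exp(-g2*||X_i - Y_j||^2)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    # ||x - y||^2 via the expansion; clip tiny negatives from rounding.
    sq = (
        (X**2).sum(axis=1)[:, None]
        + (Y**2).sum(axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(sq, 0.0, out=sq)
    return params.c * np.exp(-params.gamma1 * sq) + (1.0 - params.c) * np.exp(
        -params.gamma2 * sq
    )
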