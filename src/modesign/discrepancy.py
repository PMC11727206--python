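"""Covariate-imbalance measures.

The central quantity is the generalized (kernel) discrepancy between two
point sets, the RKHS / maximum-mean-discrepancy distance between their
empirical distributions:

    D_K(A, B)^2 = m^-2 sum K(a, a') - 2 (m l)^-1 sum K(a, b) + l^-2 sum K(b, b')

with |A| = m, |B| = l. With the kernel -||x - y|| this is the energy
distance. The classical Mahalanobis distance between group means is
provided for comparison and for re-randomization thresholds.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np

from ._validation import check_assignment, check_covariates
from .kernels import Kernel, get_kernel

__all__ = [
    "discrepancy_between_groups",
    "discrepancy_to_full",
    "discrepancy_of_assignments",
    "mahalanobis_distance",
]

# quadratic forms that should be >= 0 may go slightly negative in floating
# point; anything below this is treated as a real violation
_CLAMP = -1e-10


def _sqrt_clamped(d2: float) -> float:
    if d2 < _CLAMP:
        raise FloatingPointError(
            f"squared discrepancy is negative beyond rounding tolerance: {d2!r}"
        )
    return float(np.sqrt(max(d2, 0.0)))


def discrepancy_between_groups(g1, g0, kernel: Union[str, Kernel] = "energy") -> float:
    """Kernel discrepancy D_K(X1, X0) between two covariate groups.

    Computed by the three-term Gram-sum expansion and square-rooted, with
    tiny negative rounding errors clamped to zero. For the energy kernel
    this is the energy distance between the two empirical distributions.
    """
    g1 = check_covariates(np.atleast_2d(np.asarray(g1, dtype=float).T).T, min_rows=1)
    g0 = check_covariates(np.atleast_2d(np.asarray(g0, dtype=float).T).T, min_rows=1)
    if g1.shape[0] == 0 or g0.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    K = get_kernel(kernel)
    n1, n0 = g1.shape[0], g0.shape[0]
    d2 = (
        K.gram(g1).sum() / n1**2
        - 2.0 * K.gram(g1, g0).sum() / (n1 * n0)
        + K.gram(g0).sum() / n0**2
    )
    return _sqrt_clamped(d2)


def discrepancy_to_full(subset, full, kernel: Union[str, Kernel] = "energy") -> float:
    """Kernel discrepancy D_K(Xt, X) between a subset and the full point set.

    ``subset`` must be a (copy of a) subset of ``full``'s rows; the value is
    the RKHS distance between their empirical distributions,

        D_K(Xt, X)^2 = n^-2 sum_{x,y in X} K - 2 (n nt)^-1 sum_{x in X, y in Xt} K
                       + nt^-2 sum_{x,y in Xt} K.
    """
    full = check_covariates(full)
    subset = check_covariates(np.atleast_2d(np.asarray(subset, dtype=float).T).T,
                              min_rows=1)
    nt = subset.shape[0]
    n = full.shape[0]
    if nt == 0:
        raise ValueError("subset must be nonempty")
    K = get_kernel(kernel)
    d2 = (
        K.gram(full).sum() / n**2
        - 2.0 * K.gram(full, subset).sum() / (n * nt)
        + K.gram(subset).sum() / nt**2
    )
    return _sqrt_clamped(d2)


def discrepancy_of_assignments(
    X, T, kernel: Union[str, Kernel] = "energy", gram: Optional[np.ndarray] = None
) -> np.ndarray:
    """Group-vs-group discrepancies for a batch of assignments.

    Parameters
    ----------
    X : (n, p) array
    T : (B, n) or (n,) array of 0/1 labels, each row an assignment
    gram : optional precomputed n x n Gram matrix of the kernel on X

    Returns
    -------
    (B,) array of D_K(X1, X0) values. Vectorized so that quantiles of the
    randomization distribution of the discrepancy are cheap to estimate.
    """
    X = check_covariates(X)
    T = np.atleast_2d(np.asarray(T))
    if T.shape[1] != X.shape[0]:
        raise ValueError("assignment length does not match number of units")
    if gram is None:
        gram = get_kernel(kernel).gram(X)
    T = T.astype(float)
    n1 = T.sum(axis=1)
    n0 = T.shape[1] - n1
    if np.any(n1 == 0) or np.any(n0 == 0):
        raise ValueError("both treatment groups must be nonempty")
    KT = T @ gram                      # (B, n): row sums of K against treated
    s11 = np.einsum("bi,bi->b", KT, T)
    s_all = KT.sum(axis=1)             # treated-vs-everyone
    s10 = s_all - s11
    s00 = gram.sum() - 2.0 * s10 - s11
    d2 = s11 / n1**2 - 2.0 * s10 / (n1 * n0) + s00 / n0**2
    if d2.min() < _CLAMP:
        raise FloatingPointError("negative squared discrepancy beyond tolerance")
    return np.sqrt(np.clip(d2, 0.0, None))


def mahalanobis_distance(X, T) -> float:
    """Mahalanobis imbalance M(X1, X0) between group covariate means.

    M = (n1 n0 / n) (xbar1 - xbar0)' cov(X)^{-1} (xbar1 - xbar0),

    with the sample covariance using the n-1 denominator. A singular
    covariance falls back to the pseudo-inverse with a warning.
    """
    X = check_covariates(X)
    n, p = X.shape
    t = check_assignment(T, n)
    if n < p + 1:
        warnings.warn(
            f"n={n} <= p={p}: sample covariance is rank deficient", stacklevel=2
        )
    n1 = int(t.sum())
    n0 = n - n1
    diff = X[t == 1].mean(axis=0) - X[t == 0].mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariate covariance; using pseudo-inverse",
                      stacklevel=2)
        sol = np.linalg.pinv(cov) @ diff
    return float(n1 * n0 / n * diff @ sol)
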