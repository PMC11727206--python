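"""Treatment-assignment designs as scikit-learn-style estimators.

Each design is fit on an (n, p) covariate matrix and exposes the chosen
binary assignment as ``treatment_`` (1 = treated). Four designs are
provided:

* :class:`CompleteRandomization` — the classical CRE: a uniform draw from
  all assignments with a fixed number of treated units.
* :class:`MahalanobisRerandomization` — re-randomization (ReM): redraw the
  CRE until the Mahalanobis distance between group covariate means falls
  below a chi-square quantile threshold.
* :class:`KernelOptimalDesign` — the minimax optimal deterministic design:
  the balanced partition minimizing the kernel discrepancy between the two
  groups, found by the optimizer matched to the kernel (twinning for the
  energy kernel, CDF-transform subsampling for unit-cube kernels, Monte
  Carlo search otherwise).
* :class:`RelaxedRerandomization` — rejection sampling of CRE draws whose
  discrepancy falls below the estimated alpha-quantile of the
  randomization distribution; interpolates between the CRE (alpha = 1)
  and the deterministic optimum (alpha -> 0).

Module-level functions (:func:`cre_assign` etc.) are thin wrappers
returning the assignment vectors directly.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from ._validation import check_covariates
from .discrepancy import discrepancy_of_assignments, mahalanobis_distance
from .kernels import Kernel, get_kernel
from .partition import dds_split, mc_search, twin_split

__all__ = [
    "CompleteRandomization",
    "MahalanobisRerandomization",
    "KernelOptimalDesign",
    "RelaxedRerandomization",
    "ExternalAssignment",
    "cre_assign",
    "rem_assign",
    "mode_assign",
    "relaxed_rerandomize",
    "rem_threshold",
    "make_design",
]


def rem_threshold(p: int, q: float = 0.2) -> float:
    """The q-quantile of the chi-square distribution with p df.

    Used as the re-randomization acceptance threshold: the Mahalanobis
    imbalance of a balanced CRE is asymptotically chi-square with p df, so
    accepting draws below this threshold accepts a fraction ~q of them.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(chi2.ppf(q, df=p))


def _draw_balanced(rng: np.random.Generator, n: int, n1: int) -> np.ndarray:
    t = np.zeros(n, dtype=np.int64)
    t[rng.choice(n, size=n1, replace=False)] = 1
    return t


def _draw_balanced_batch(rng: np.random.Generator, n: int, n1: int,
                         size: int) -> np.ndarray:
    order = rng.random((size, n)).argpartition(n1 - 1, axis=1)
    T = np.zeros((size, n), dtype=np.int64)
    np.put_along_axis(T, order[:, :n1], 1, axis=1)
    return T


class _BaseDesign(BaseEstimator):
    """Shared fit/predict plumbing; subclasses implement ``_assign``."""

    def fit(self, X, y=None):
        X = check_covariates(X)
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.treatment_ = self._assign(X, rng)
        self.n_treated_ = int(self.treatment_.sum())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).treatment_

    def _assign(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class CompleteRandomization(_BaseDesign):
    """Completely randomized experiment with fixed group sizes.

    Parameters
    ----------
    n1 : int, optional
        Number of treated units; defaults to the balanced floor(n/2).
    random_state : int or Generator, optional
    """

    def __init__(self, n1: Optional[int] = None, random_state=None):
        self.n1 = n1
        self.random_state = random_state

    def _assign(self, X, rng):
        n = X.shape[0]
        n1 = n // 2 if self.n1 is None else int(self.n1)
        if not 1 <= n1 <= n - 1:
            raise ValueError(f"n1 must be in [1, {n - 1}], got {n1}")
        return _draw_balanced(rng, n, n1)


class MahalanobisRerandomization(_BaseDesign):
    """Balanced re-randomization with a Mahalanobis acceptance region (ReM).

    Redraws balanced CRE assignments until M(X1, X0) <= threshold. The
    default threshold is the ``acceptance``-quantile of chi-square(p), so
    roughly that fraction of draws is accepted.

    Fitted attributes: ``treatment_``, ``threshold_``, ``n_draws_``,
    ``mahalanobis_``.
    """

    def __init__(self, acceptance: float = 0.2, threshold: Optional[float] = None,
                 max_draws: int = 100_000, random_state=None):
        self.acceptance = acceptance
        self.threshold = threshold
        self.max_draws = max_draws
        self.random_state = random_state

    def _assign(self, X, rng):
        n, p = X.shape
        a = self.threshold if self.threshold is not None else rem_threshold(
            p, self.acceptance)
        if not a > 0:
            raise ValueError("threshold must be positive")
        n1 = n // 2
        for draw in range(1, int(self.max_draws) + 1):
            t = _draw_balanced(rng, n, n1)
            m = mahalanobis_distance(X, t)
            if m <= a:
                self.threshold_ = float(a)
                self.n_draws_ = draw
                self.mahalanobis_ = m
                return t
        raise RuntimeError(
            f"no assignment accepted after {self.max_draws} draws "
            f"(threshold {a:.4g}; empirical acceptance rate < "
            f"{1.0 / self.max_draws:.2e})"
        )


class KernelOptimalDesign(_BaseDesign):
    """Minimax optimal deterministic design (MODE).

    Fits the balanced partition minimizing the kernel discrepancy between
    the treated and control covariates, dispatching by kernel: a
    twinning-style nearest-neighbour split for the energy kernel, the
    marginal-CDF-transform split for unit-cube kernels, and best-of-M
    Monte Carlo search otherwise. Treated units are the optimized subset
    X1*; the worst-case MSE over the RKHS ball of mean functions is
    sigma^2 (1/n1 + 1/n0) + gamma^2 D_K(X1, X0)^2, so minimizing the
    discrepancy minimizes the maximum risk among balanced designs.

    Fitted attributes: ``treatment_``, ``discrepancy_``, ``method_``,
    ``partition_``.
    """

    def __init__(self, kernel: Union[str, Kernel] = "energy", M: int = 500,
                 max_passes: int = 50, random_state=None):
        self.kernel = kernel
        self.M = M
        self.max_passes = max_passes
        self.random_state = random_state

    def _assign(self, X, rng):
        if X.shape[0] < 4:
            raise ValueError("the optimal design needs at least 4 units")
        K = get_kernel(self.kernel)
        seed = int(rng.integers(2**31 - 1))
        if K.kind == "energy":
            res = twin_split(X, K, seed=seed, polish_passes=self.max_passes)
        elif K.unit_cube:
            res = dds_split(X, K, seed=seed, max_passes=self.max_passes)
        else:
            res = mc_search(X, K, M=self.M, seed=seed)
        self.partition_ = res
        self.discrepancy_ = res.discrepancy
        self.method_ = res.method
        return res.labels


class RelaxedRerandomization(_BaseDesign):
    """Discrepancy-thresholded re-randomization.

    Estimates the alpha-quantile q of the kernel discrepancy over random
    balanced assignments (``n_quantile_draws`` Monte Carlo draws), then
    rejection-samples CRE draws until D_K(X1, X0) <= q. With alpha = 1
    this is the CRE; as alpha -> 0 it concentrates on the deterministic
    optimum while retaining randomization.

    Fitted attributes: ``treatment_``, ``quantile_``, ``n_draws_``,
    ``discrepancy_``.
    """

    def __init__(self, kernel: Union[str, Kernel] = "energy", alpha: float = 0.1,
                 n_quantile_draws: int = 1000, max_draws: int = 100_000,
                 random_state=None):
        self.kernel = kernel
        self.alpha = alpha
        self.n_quantile_draws = n_quantile_draws
        self.max_draws = max_draws
        self.random_state = random_state

    def _assign(self, X, rng):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        n = X.shape[0]
        n1 = n // 2
        if self.alpha >= 1.0:
            self.quantile_ = np.inf
            self.n_draws_ = 1
            t = _draw_balanced(rng, n, n1)
            self.discrepancy_ = float(
                discrepancy_of_assignments(X, t, kernel=self.kernel)[0])
            return t
        gram = get_kernel(self.kernel).gram(X)
        ref = _draw_balanced_batch(rng, n, n1, int(self.n_quantile_draws))
        d_ref = discrepancy_of_assignments(X, ref, gram=gram)
        q = float(np.quantile(d_ref, self.alpha))
        for draw in range(1, int(self.max_draws) + 1):
            t = _draw_balanced(rng, n, n1)
            d = float(discrepancy_of_assignments(X, t, gram=gram)[0])
            if d <= q:
                self.quantile_ = q
                self.n_draws_ = draw
                self.discrepancy_ = d
                return t
        raise RuntimeError(
            f"no assignment accepted after {self.max_draws} draws "
            f"(discrepancy quantile {q:.4g} at alpha={self.alpha})"
        )


class ExternalAssignment(_BaseDesign):
    """Carry a pre-computed assignment (e.g. a competitor design read from
    file) through the simulation harness."""

    def __init__(self, labels=None, random_state=None):
        self.labels = labels
        self.random_state = random_state

    def _assign(self, X, rng):
        from ._validation import check_assignment

        if self.labels is None:
            raise ValueError("ExternalAssignment requires a labels vector")
        return check_assignment(self.labels, X.shape[0])


# ---------------------------------------------------------------------------
# thin functional interface


def cre_assign(n: int, n1: Optional[int] = None, seed=None) -> np.ndarray:
    """Uniform random assignment with n1 treated units (default n//2)."""
    if n < 2:
        raise ValueError("need at least 2 units")
    n1 = n // 2 if n1 is None else int(n1)
    if not 1 <= n1 <= n - 1:
        raise ValueError(f"n1 must be in [1, {n - 1}], got {n1}")
    return _draw_balanced(np.random.default_rng(seed), n, n1)


def rem_assign(X, a: float, seed=None, max_draws: int = 100_000) -> np.ndarray:
    """Balanced ReM draw: first CRE draw with Mahalanobis distance <= a."""
    est = MahalanobisRerandomization(threshold=a, max_draws=max_draws,
                                     random_state=seed)
    return est.fit_predict(X)


def mode_assign(X, kernel: Union[str, Kernel] = "energy", M: int = 500,
                seed=None) -> np.ndarray:
    """Minimax optimal deterministic assignment (treated = optimized X1*)."""
    est = KernelOptimalDesign(kernel=kernel, M=M, random_state=seed)
    return est.fit_predict(X)


def relaxed_rerandomize(X, kernel: Union[str, Kernel] = "energy",
                        alpha: float = 0.1, n_quantile_draws: int = 1000,
                        seed=None, max_draws: int = 100_000) -> np.ndarray:
    """Discrepancy-thresholded re-randomization draw."""
    est = RelaxedRerandomization(kernel=kernel, alpha=alpha,
                                 n_quantile_draws=n_quantile_draws,
                                 max_draws=max_draws, random_state=seed)
    return est.fit_predict(X)


_DESIGNS = {
    "cre": CompleteRandomization,
    "rem": MahalanobisRerandomization,
    "mode": KernelOptimalDesign,
    "mode_relaxed": RelaxedRerandomization,
    "mode-relaxed": RelaxedRerandomization,
    "external": ExternalAssignment,
}


def make_design(name: str, **params) -> _BaseDesign:
    """Instantiate a design estimator by name (cre, rem, mode, mode_relaxed,
    external)."""
    try:
        cls = _DESIGNS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; choose from {sorted(set(_DESIGNS))}"
        ) from None
    return cls(**params)
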