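"""Estimators and risk decompositions for two-arm designs.

Under the potential-outcomes model E(Y(t)|X) = f_t(X), var(Y(t)|X) =
sigma_t^2(X), the conditional MSE of the difference-in-means estimator
given an assignment splits into a sampling-variance term and a squared
bias term. Taking the worst case over mean functions in an RKHS ball of
radius gamma and variance functions bounded by sigma^2 gives the maximum
risk

    R(T) = sigma^2 (1/n1 + 1/n0) + gamma^2 D_K(X1, X0)^2,

computable from the kernel discrepancy alone. For the completely
randomized experiment the randomization variance decomposes into a
fixed-potential-outcome part (EV) and a noise part (VE); the percent
reduction statistic compares a candidate design's MSE against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Union

import numpy as np
from scipy.stats import chi2

from ._validation import check_assignment, check_covariates
from .discrepancy import discrepancy_between_groups, discrepancy_to_full
from .kernels import Kernel

__all__ = [
    "RiskParams",
    "OutcomeModel",
    "RiskReport",
    "difference_in_means",
    "true_ate",
    "conditional_mse",
    "max_risk",
    "max_risk_split_form",
    "randomization_variance",
    "enumerate_assignment_moments",
    "percent_reduction",
    "va_factor",
]

ENUMERATION_MAX_N = 14


@dataclass
class RiskParams:
    """Bounds defining the worst-case outcome-function class.

    sigma2 bounds the conditional outcome variance in both arms; gamma2
    bounds the squared RKHS norm of both mean functions under ``kernel``.
    """

    sigma2: float
    gamma2: float
    kernel: Union[str, Kernel] = "energy"

    def __post_init__(self):
        if not (np.isfinite(self.sigma2) and self.sigma2 >= 0):
            raise ValueError("sigma2 must be finite and nonnegative")
        if not (np.isfinite(self.gamma2) and self.gamma2 >= 0):
            raise ValueError("gamma2 must be finite and nonnegative")


@dataclass
class OutcomeModel:
    """Mean and variance functions of the two potential outcomes.

    Each function maps an (n, p) covariate matrix to an (n,) vector;
    simulation noise is Gaussian with the given variance functions.
    """

    f1: Callable[[np.ndarray], np.ndarray]
    f0: Callable[[np.ndarray], np.ndarray]
    s1sq: Callable[[np.ndarray], np.ndarray]
    s0sq: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    def _eval(self, func, X) -> np.ndarray:
        out = np.broadcast_to(np.asarray(func(X), dtype=float), (X.shape[0],)).copy()
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(f"{self.name}: non-finite model value")
        return out

    def means(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = check_covariates(X)
        return self._eval(self.f1, X), self._eval(self.f0, X)

    def variances(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = check_covariates(X)
        v1, v0 = self._eval(self.s1sq, X), self._eval(self.s0sq, X)
        if v1.min() < 0 or v0.min() < 0:
            raise ValueError("variance functions must be nonnegative")
        return v1, v0


@dataclass
class RiskReport:
    """Additive decomposition of a (maximum) risk into variance and bias."""

    variance_component: float
    bias_component: float

    @property
    def total(self) -> float:
        return self.variance_component + self.bias_component

    def to_dict(self) -> dict:
        return {
            "variance_component": self.variance_component,
            "bias_component": self.bias_component,
            "total": self.total,
        }


def difference_in_means(T, Y) -> float:
    """Treated-group mean outcome minus control-group mean outcome."""
    Y = np.asarray(Y, dtype=float)
    t = check_assignment(T, Y.shape[0] if Y.ndim == 1 else None)
    if Y.ndim != 1 or Y.shape[0] != t.shape[0]:
        raise ValueError("Y must be a vector matching the assignment length")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    return float(Y[t == 1].mean() - Y[t == 0].mean())


def true_ate(X, model: OutcomeModel) -> float:
    """Finite-population average treatment effect: mean of f1(X) - f0(X)."""
    f1, f0 = model.means(X)
    return float((f1 - f0).mean())


def conditional_mse(T, X, model: OutcomeModel) -> tuple[float, float]:
    """Conditional variance V and squared bias B of the difference-in-means
    estimator given a fixed assignment; MSE = V + B."""
    X = check_covariates(X)
    t = check_assignment(T, X.shape[0])
    f1, f0 = model.means(X)
    v1, v0 = model.variances(X)
    n1 = int(t.sum())
    n0 = t.shape[0] - n1
    V = float(v1[t == 1].sum() / n1**2 + v0[t == 0].sum() / n0**2)
    tau = float((f1 - f0).mean())
    contrast = float(f1[t == 1].mean() - f0[t == 0].mean())
    B = (contrast - tau) ** 2
    return V, B


def max_risk(T, X, params: RiskParams) -> RiskReport:
    """Worst-case MSE of the difference-in-means estimator over the class
    defined by ``params``.

    The bias component is gamma^2 D_K(X1, X0)^2; by the splitting identity
    this equals gamma^2 (D_K(X1, X) + D_K(X0, X))^2.
    """
    X = check_covariates(X)
    t = check_assignment(T, X.shape[0])
    n1 = int(t.sum())
    n0 = t.shape[0] - n1
    var = params.sigma2 * (1.0 / n1 + 1.0 / n0)
    d = discrepancy_between_groups(X[t == 1], X[t == 0], params.kernel)
    return RiskReport(variance_component=var, bias_component=params.gamma2 * d**2)


def max_risk_split_form(T, X, params: RiskParams) -> RiskReport:
    """Same maximum risk computed from the subset-vs-full discrepancies;
    agrees with :func:`max_risk` up to rounding (used as a cross-check)."""
    X = check_covariates(X)
    t = check_assignment(T, X.shape[0])
    n1 = int(t.sum())
    n0 = t.shape[0] - n1
    var = params.sigma2 * (1.0 / n1 + 1.0 / n0)
    d1 = discrepancy_to_full(X[t == 1], X, params.kernel)
    d0 = discrepancy_to_full(X[t == 0], X, params.kernel)
    return RiskReport(variance_component=var,
                      bias_component=params.gamma2 * (d1 + d0) ** 2)


def randomization_variance(X, model: OutcomeModel, n1: int) -> tuple[float, float]:
    """(EV, VE) decomposition of the CRE randomization variance.

    EV = S^2(f1)/n1 + S^2(f0)/n0 - S^2(f1, f0)/n  (fixed potential outcomes)
    VE = (sum sigma1^2)/(n n1) + (sum sigma0^2)/(n n0)  (outcome noise)

    with S^2 the n-1-denominator finite-population variances of the mean
    functions and of the unit-level effects.
    """
    X = check_covariates(X)
    n = X.shape[0]
    if not 1 <= n1 <= n - 1:
        raise ValueError(f"n1 must be in [1, {n - 1}]")
    n0 = n - n1
    f1, f0 = model.means(X)
    v1, v0 = model.variances(X)
    s2_f1 = float(np.var(f1, ddof=1))
    s2_f0 = float(np.var(f0, ddof=1))
    s2_tau = float(np.var(f1 - f0, ddof=1))
    ev = s2_f1 / n1 + s2_f0 / n0 - s2_tau / n
    ve = v1.sum() / (n * n1) + v0.sum() / (n * n0)
    return float(ev), float(ve)


def enumerate_assignment_moments(X, model: OutcomeModel,
                                 n1: int) -> tuple[float, float]:
    """Exact mean and variance of the difference-in-means estimator over
    all C(n, n1) assignments (n <= 14 guard).

    The deterministic contrast is enumerated exactly; independent outcome
    noise contributes its analytic average variance (the VE term).
    """
    X = check_covariates(X)
    n = X.shape[0]
    if n > ENUMERATION_MAX_N:
        raise ValueError(f"enumeration is limited to n <= {ENUMERATION_MAX_N}")
    if not 1 <= n1 <= n - 1:
        raise ValueError(f"n1 must be in [1, {n - 1}]")
    f1, f0 = model.means(X)
    v1, v0 = model.variances(X)
    n0 = n - n1
    total0 = f0.sum()
    vals = []
    for c in combinations(range(n), n1):
        idx = list(c)
        vals.append(f1[idx].sum() / n1 - (total0 - f0[idx].sum()) / n0)
    vals = np.asarray(vals)
    ve = v1.sum() / (n * n1) + v0.sum() / (n * n0)
    return float(vals.mean()), float(vals.var(ddof=0) + ve)


def percent_reduction(var_cre: float, mse_mode: float) -> float:
    """100 (var_cre - mse_mode) / var_cre; negative if the candidate design
    does worse than the CRE."""
    if not var_cre > 0:
        raise ValueError("var_cre must be positive")
    return float(100.0 * (var_cre - mse_mode) / var_cre)


def va_factor(p: int, a: float) -> float:
    """Variance-reduction multiplier of balanced re-randomization:
    P(chi2_{p+2} <= a) / P(chi2_p <= a), in (0, 1)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not a > 0:
        raise ValueError("a must be positive")
    return float(chi2.cdf(a, df=p + 2) / chi2.cdf(a, df=p))
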