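"""Synthetic covariates, outcome models, and the replication engine.

The study conditions emulated here: covariates drawn iid from U[-3, 3] or
N(0, variance 3); four potential-outcome specifications (C1-C4) whose mean
functions depend on the covariates only through the row average
x~ = sum_j x_j / p,

    C1: f1 = exp(x~),            f0 = 1 + x~,              no noise
    C2: C1 means,                unit-variance noise in both arms
    C3: f1 = exp(x~)+exp(x~/2),  f0 = exp(x~)-exp(x~/2),   no noise
    C4: C3 means,                unit-variance noise in both arms

with independent standard normal noise per unit and arm. The replication
engine redraws covariates each replication, runs each configured design on
the same draw (paired comparison), and aggregates the empirical MSE of the
difference-in-means estimator and the Kolmogorov-Smirnov distance between
the treatment-arm potential outcomes and the observed treated outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import clone

from ._validation import check_assignment, check_covariates
from .designs import _BaseDesign, make_design
from .risk import OutcomeModel, difference_in_means, true_ate

__all__ = [
    "gen_covariates",
    "outcome_model",
    "eval_model",
    "gen_outcomes",
    "ks_statistic",
    "SimulationConfig",
    "SimulationResult",
    "run_study",
]

logger = logging.getLogger(__name__)


def gen_covariates(n: int, p: int, law: str = "uniform", seed=None) -> np.ndarray:
    """Draw an (n, p) covariate matrix with iid entries.

    ``law``: "uniform" = U[-3, 3]; "normal" = N(0, variance 3). Both laws
    have mean 0 and variance 3 so they are moment-comparable.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 and p >= 1")
    rng = np.random.default_rng(seed)
    if law == "uniform":
        return rng.uniform(-3.0, 3.0, size=(n, p))
    if law == "normal":
        return rng.normal(0.0, np.sqrt(3.0), size=(n, p))
    raise ValueError(f"unknown covariate law {law!r}; use 'uniform' or 'normal'")


def _xtilde(X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float).mean(axis=1)


_MODELS = {
    "C1": (lambda X: np.exp(_xtilde(X)), lambda X: 1.0 + _xtilde(X), 0.0),
    "C2": (lambda X: np.exp(_xtilde(X)), lambda X: 1.0 + _xtilde(X), 1.0),
    "C3": (lambda X: np.exp(_xtilde(X)) + np.exp(_xtilde(X) / 2.0),
           lambda X: np.exp(_xtilde(X)) - np.exp(_xtilde(X) / 2.0), 0.0),
    "C4": (lambda X: np.exp(_xtilde(X)) + np.exp(_xtilde(X) / 2.0),
           lambda X: np.exp(_xtilde(X)) - np.exp(_xtilde(X) / 2.0), 1.0),
}


def outcome_model(model_id: str) -> OutcomeModel:
    """The named potential-outcome specification as an :class:`OutcomeModel`."""
    key = model_id.upper()
    if key not in _MODELS:
        raise ValueError(f"unknown model {model_id!r}; choose from C1..C4")
    f1, f0, s2 = _MODELS[key]
    return OutcomeModel(
        f1=f1,
        f0=f0,
        s1sq=lambda X, _s=s2: np.full(X.shape[0], _s),
        s0sq=lambda X, _s=s2: np.full(X.shape[0], _s),
        name=key,
    )


def eval_model(model_id: str, x) -> tuple[float, float, float, float]:
    """Evaluate (f1, f0, sigma1^2, sigma0^2) of a named model at one point."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m = outcome_model(model_id)
    return (float(np.ravel(m.f1(x))[0]), float(np.ravel(m.f0(x))[0]),
            float(np.ravel(m.s1sq(x))[0]), float(np.ravel(m.s0sq(x))[0]))


def gen_outcomes(X, model: Union[str, OutcomeModel], T, seed=None):
    """Draw potential outcomes and compose the observed outcome vector.

    Returns (Y, Y1, Y0) with Y1 = f1(X) + sigma1(X) u, Y0 = f0(X) + sigma0(X) v,
    u, v iid N(0, 1), and Y = T*Y1 + (1-T)*Y0.
    """
    X = check_covariates(X)
    t = check_assignment(T, X.shape[0])
    m = outcome_model(model) if isinstance(model, str) else model
    f1, f0 = m.means(X)
    v1, v0 = m.variances(X)
    rng = np.random.default_rng(seed)
    y1 = f1 + np.sqrt(v1) * rng.standard_normal(X.shape[0])
    y0 = f0 + np.sqrt(v0) * rng.standard_normal(X.shape[0])
    y = np.where(t == 1, y1, y0)
    return y, y1, y0


def ks_statistic(potential, observed) -> float:
    """Two-sample Kolmogorov-Smirnov distance sup_y |F(y) - Fn(y)| between
    the empirical CDFs of the two vectors."""
    a = np.sort(np.asarray(potential, dtype=float))
    b = np.sort(np.asarray(observed, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(fa - fb).max())


@dataclass
class SimulationConfig:
    """Settings for one simulation study cell.

    ``model`` is a named specification ("C1".."C4") or any
    :class:`~modesign.risk.OutcomeModel` instance.
    """

    n: int
    p: int
    model: Union[str, OutcomeModel] = "C1"
    covariate_law: str = "uniform"
    designs: Sequence = ("cre", "mode")
    replications: int = 1000
    seed: int = 0
    redraw_covariates: bool = True

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.n % 2 != 0:
            raise ValueError("balanced designs require an even n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def _normalize_designs(designs) -> list[tuple[str, _BaseDesign]]:
    out = []
    for item in designs:
        if isinstance(item, str):
            out.append((item, make_design(item)))
        elif isinstance(item, dict):
            spec = dict(item)
            name = spec.pop("name")
            label = spec.pop("label", name)
            out.append((label, make_design(name, **spec)))
        elif isinstance(item, tuple) and len(item) == 2:
            out.append((item[0], item[1]))
        elif isinstance(item, _BaseDesign):
            out.append((type(item).__name__, item))
        else:
            raise TypeError(f"cannot interpret design spec {item!r}")
    labels = [lab for lab, _ in out]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate design labels: {labels}")
    return out


@dataclass
class SimulationResult:
    """Per-replication records and per-design summaries of one study cell."""

    config: SimulationConfig
    records: pd.DataFrame  # columns: replication, design, sq_error, ks
    n_failed: int = 0
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = []
        grouped = self.records.groupby("design", sort=False)
        mse_cre = None
        if "cre" in self.records["design"].values:
            mse_cre = grouped.get_group("cre")["sq_error"].mean()
        for design, g in grouped:
            r = len(g)
            mse = g["sq_error"].mean()
            row = {
                "design": design,
                "replications": r,
                "mse": mse,
                "mse_se": g["sq_error"].std(ddof=1) / np.sqrt(r),
                "mean_ks": g["ks"].mean(),
                "ks_se": g["ks"].std(ddof=1) / np.sqrt(r),
            }
            row["pr_vs_cre"] = (
                100.0 * (mse_cre - mse) / mse_cre if mse_cre else np.nan
            )
            rows.append(row)
        self.summary = pd.DataFrame(rows).set_index("design")

    def mse(self, design: str) -> float:
        return float(self.summary.loc[design, "mse"])

    def mse_se(self, design: str) -> float:
        return float(self.summary.loc[design, "mse_se"])

    def mean_ks(self, design: str) -> float:
        return float(self.summary.loc[design, "mean_ks"])

    def ks_se(self, design: str) -> float:
        return float(self.summary.loc[design, "ks_se"])

    def pr(self, design: str) -> float:
        """Percent reduction in empirical MSE of ``design`` relative to CRE."""
        return float(self.summary.loc[design, "pr_vs_cre"])

    def format_table(self) -> str:
        """One-cell summary in the conventional layout: per design the
        empirical MSE (x 1e4), mean KS distance (x 1e2), and percent
        reduction versus CRE."""
        c = self.config
        model_name = c.model if isinstance(c.model, str) else c.model.name
        lines = [f"{model_name}, p={c.p}, n={c.n} "
                 f"({self.summary['replications'].max()} replications)",
                 f"{'design':<14}{'MSE x1e4':>10}{'KS x1e2':>9}{'PR %':>7}"]
        for design, s in self.summary.iterrows():
            pr = "" if np.isnan(s["pr_vs_cre"]) else f"{s['pr_vs_cre']:7.1f}"
            lines.append(f"{design:<14}{s['mse'] * 1e4:10.1f}"
                         f"{s['mean_ks'] * 1e2:9.2f}{pr}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (design, metric, value, mc_se) table, with the conventional
        display scalings (MSE x 1e4, KS x 1e2) applied."""
        rows = []
        c = self.config
        model_name = c.model if isinstance(c.model, str) else c.model.name
        for design, s in self.summary.iterrows():
            base = {"model": model_name, "n": c.n, "p": c.p, "design": design}
            rows.append({**base, "metric": "mse_x1e4", "value": s["mse"] * 1e4,
                         "mc_se": s["mse_se"] * 1e4})
            rows.append({**base, "metric": "ks_x1e2", "value": s["mean_ks"] * 1e2,
                         "mc_se": s["ks_se"] * 1e2})
            rows.append({**base, "metric": "pr_vs_cre_pct", "value": s["pr_vs_cre"],
                         "mc_se": np.nan})
        return pd.DataFrame(rows)


def run_study(config: SimulationConfig) -> SimulationResult:
    """Run one simulation cell: per replication, (re)draw covariates, fit
    every design on the same draw, draw one shared set of outcome noise,
    and record each design's squared estimation error and treated-group
    Kolmogorov-Smirnov distance."""
    designs = _normalize_designs(config.designs)
    model = (outcome_model(config.model) if isinstance(config.model, str)
             else config.model)
    root = np.random.SeedSequence(config.seed)
    fixed_X = None
    if not config.redraw_covariates:
        fixed_X = gen_covariates(config.n, config.p, config.covariate_law,
                                 seed=root.spawn(1)[0])
    records = []
    n_failed = 0
    for rep in range(config.replications):
        ss = np.random.SeedSequence([config.seed, rep])
        streams = ss.spawn(2 + len(designs))
        try:
            X = fixed_X if fixed_X is not None else gen_covariates(
                config.n, config.p, config.covariate_law, seed=streams[0])
            f1, f0 = model.means(X)
            v1, v0 = model.variances(X)
            noise_rng = np.random.default_rng(streams[1])
            y1 = f1 + np.sqrt(v1) * noise_rng.standard_normal(config.n)
            y0 = f0 + np.sqrt(v0) * noise_rng.standard_normal(config.n)
            tau = float((f1 - f0).mean())
            for (label, est), stream in zip(designs, streams[2:]):
                e = clone(est)
                e.set_params(random_state=np.random.default_rng(stream))
                t = e.fit_predict(X)
                y = np.where(t == 1, y1, y0)
                tau_hat = float(y[t == 1].mean() - y[t == 0].mean())
                records.append({
                    "replication": rep,
                    "design": label,
                    "sq_error": (tau_hat - tau) ** 2,
                    "ks": ks_statistic(y1, y[t == 1]),
                })
        except Exception:
            n_failed += 1
            logger.exception("replication %d failed", rep)
            if n_failed > max(1, config.replications // 100):
                raise RuntimeError(
                    f"{n_failed} of {rep + 1} replications failed; aborting"
                )
    return SimulationResult(config=config, records=pd.DataFrame(records),
                            n_failed=n_failed)
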