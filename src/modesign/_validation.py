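"""Input validation shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["check_covariates", "check_assignment"]


def check_covariates(X, min_rows: int = 2) -> np.ndarray:
    """Validate an n x p covariate matrix: 2-D, finite, n >= min_rows, p >= 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"covariates must be a 2-D matrix, got ndim={X.ndim}")
    n, p = X.shape
    if n < min_rows:
        raise ValueError(f"need at least {min_rows} units, got {n}")
    if p < 1:
        raise ValueError("need at least one covariate")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain NaN or infinite entries")
    return X


def check_assignment(t, n: int | None = None) -> np.ndarray:
    """Validate a binary treatment vector with both groups nonempty."""
    t = np.asarray(t)
    if t.ndim != 1:
        raise ValueError("treatment assignment must be a 1-D vector")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("treatment labels must be 0 or 1")
    t = t.astype(np.int64)
    if n is not None and t.shape[0] != n:
        raise ValueError(f"assignment length {t.shape[0]} != number of units {n}")
    n1 = int(t.sum())
    if n1 == 0 or n1 == t.shape[0]:
        raise ValueError("both treatment groups must be nonempty")
    return t
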