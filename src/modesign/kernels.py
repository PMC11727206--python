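"""Reproducing kernels on covariate space.

A kernel ``K(x, y)`` defines the function class over which the worst-case
estimation risk of a design is taken: the bias of the difference-in-means
estimator over all mean functions with RKHS norm at most ``gamma`` is
``gamma`` times the kernel discrepancy between the two treatment groups.
Two named kernels are provided — the (negative) Euclidean distance kernel,
whose discrepancy is the energy distance, and the centered-L2 kernel on the
unit cube from the quasi-Monte Carlo literature — plus a wrapper for
arbitrary user-supplied symmetric kernels.
"""

from __future__ import annotations

from typing import Callable, Optional, Union

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Kernel",
    "EnergyKernel",
    "CenteredL2Kernel",
    "UserKernel",
    "kernel_energy",
    "kernel_centered_l2",
    "get_kernel",
]


class Kernel:
    """Base class for symmetric kernels on R^p.

    Subclasses implement :meth:`gram`; :meth:`__call__` evaluates single
    pairs through it.

    Attributes
    ----------
    kind : str
        One of ``"energy"``, ``"centered_l2"``, ``"user"``; drives the
        optimizer dispatch of the design algorithm.
    unit_cube : bool
        Whether the kernel's domain is [0, 1]^p (such kernels are applied
        to rank-transformed covariates by the design algorithm).
    """

    kind: str = "user"
    unit_cube: bool = False

    def gram(self, A: np.ndarray, B: Optional[np.ndarray] = None) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, y) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if x.shape != y.shape:
            raise ValueError(
                f"kernel arguments must have equal length, got {x.shape} and {y.shape}"
            )
        return float(self.gram(x[None, :], y[None, :])[0, 0])

    def _validate(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise ValueError("expected a 2-D array of points")
        if not np.all(np.isfinite(A)):
            raise ValueError("kernel inputs must be finite")
        return A

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}()"


class EnergyKernel(Kernel):
    """K(x, y) = -||x - y||_2, the conditionally positive definite kernel
    whose induced discrepancy between two point sets is the energy distance.

    Nonpositive everywhere; zero iff x == y.
    """

    kind = "energy"
    unit_cube = False

    def gram(self, A, B=None):
        A = self._validate(A)
        B = A if B is None else self._validate(B)
        if A.shape[1] != B.shape[1]:
            raise ValueError("point sets differ in dimension")
        return -cdist(A, B)


class CenteredL2Kernel(Kernel):
    """Kernel of the centered L2-discrepancy on [0, 1]^p:

    K(x, y) = prod_j (1 + 0.5|x_j - 0.5| + 0.5|y_j - 0.5| - 0.5|x_j - y_j|)

    Inputs outside the unit cube are a domain error.
    """

    kind = "centered_l2"
    unit_cube = True

    def gram(self, A, B=None):
        A = self._validate(A)
        B = A if B is None else self._validate(B)
        if A.shape[1] != B.shape[1]:
            raise ValueError("point sets differ in dimension")
        for M in (A, B):
            if M.min() < 0.0 or M.max() > 1.0:
                raise ValueError("centered-L2 kernel requires inputs in [0, 1]^p")
        out = np.ones((A.shape[0], B.shape[0]))
        # accumulate the product one coordinate at a time to keep memory at O(n^2)
        for j in range(A.shape[1]):
            a = A[:, j][:, None]
            b = B[:, j][None, :]
            out *= (
                1.0
                + 0.5 * np.abs(a - 0.5)
                + 0.5 * np.abs(b - 0.5)
                - 0.5 * np.abs(a - b)
            )
        return out


class UserKernel(Kernel):
    """Wrap an arbitrary symmetric function ``f(x, y) -> float`` as a kernel.

    Evaluated pointwise, so quadratic-form computations cost O(n^2) calls;
    intended for small problems and custom discrepancies (e.g. kernels for
    discrete covariates).
    """

    kind = "user"

    def __init__(self, func: Callable[[np.ndarray, np.ndarray], float],
                 unit_cube: bool = False, name: str = "user"):
        self.func = func
        self.unit_cube = unit_cube
        self.name = name

    def gram(self, A, B=None):
        A = self._validate(A)
        B = A if B is None else self._validate(B)
        out = np.empty((A.shape[0], B.shape[0]))
        for i in range(A.shape[0]):
            for k in range(B.shape[0]):
                out[i, k] = self.func(A[i], B[k])
        if not np.all(np.isfinite(out)):
            raise ValueError("user kernel returned non-finite values")
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"UserKernel({self.name!r})"


def kernel_energy(x, y) -> float:
    """Negative Euclidean distance between two points."""
    return EnergyKernel()(x, y)


def kernel_centered_l2(x, y) -> float:
    """Centered-L2 kernel factor product; x, y must lie in [0, 1]^p."""
    return CenteredL2Kernel()(x, y)


_NAMED = {
    "energy": EnergyKernel,
    "centered_l2": CenteredL2Kernel,
    "centered-l2": CenteredL2Kernel,
}


def get_kernel(kernel: Union[str, Kernel, Callable]) -> Kernel:
    """Resolve a kernel argument: a :class:`Kernel`, a name, or a callable."""
    if isinstance(kernel, Kernel):
        return kernel
    if isinstance(kernel, str):
        try:
            return _NAMED[kernel.lower()]()
        except KeyError:
            raise ValueError(
                f"unknown kernel {kernel!r}; choose from {sorted(set(_NAMED))}"
            ) from None
    if callable(kernel):
        return UserKernel(kernel)
    raise TypeError(f"cannot interpret {kernel!r} as a kernel")
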