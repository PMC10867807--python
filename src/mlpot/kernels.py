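"""Kernel functions for kernel ridge regression, with derivatives.

Seven families are available.  With d = ||x - x_j||_2 (L1 for Laplacian):

* linear:             k = x . x_j
* gaussian:           k = exp(-d^2 / (2 sigma^2))
* exponential:        k = exp(-d / sigma)
* laplacian:          k = exp(-||x - x_j||_1 / sigma)
* matern:             k = exp(-d/sigma) * sum_{k=0..n} (n+k)!/(2n)! C(n,k) (2d/sigma)^(n-k)
* periodic:           k = exp(-2 sin^2(pi d / p) / sigma^2)
* decaying_periodic:  gaussian(sigma) * periodic(sigma_p, p)

Matern with n = 0 collapses to the exponential kernel; the decaying
periodic kernel approaches the Gaussian as the period p grows.

``kernel_derivatives`` supplies the gradient with respect to the first
argument and the mixed second-derivative block d^2 k / (dx dx_j) needed for
training on energy gradients: analytic for the Gaussian family, central
finite differences for the rest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "kernel_value",
    "kernel_matrix",
    "kernel_derivatives",
]

FAMILIES = (
    "linear",
    "gaussian",
    "exponential",
    "laplacian",
    "matern",
    "periodic",
    "decaying_periodic",
)

_NEEDS_SIGMA = set(FAMILIES) - {"linear"}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters.

    sigma: length scale (> 0; all families except linear).
    n: non-negative integer smoothness order (matern only).
    p: period (> 0; periodic families).
    sigma_p: length scale of the periodic factor (decaying_periodic only).
    """

    family: str = "gaussian"
    sigma: float | None = None
    n: int | None = None
    p: float | None = None
    sigma_p: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family in _NEEDS_SIGMA:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError(f"{self.family} kernel requires sigma > 0")
        if self.family == "matern":
            if self.n is None or self.n < 0 or int(self.n) != self.n:
                raise ValueError("matern requires a non-negative integer n")
        if self.family in ("periodic", "decaying_periodic"):
            if self.p is None or self.p <= 0:
                raise ValueError("periodic kernels require period p > 0")
        if self.family == "decaying_periodic":
            if self.sigma_p is None or self.sigma_p <= 0:
                raise ValueError("decaying_periodic requires sigma_p > 0")

    def replace(self, **kw) -> "KernelSpec":
        from dataclasses import replace

        return replace(self, **kw)


def _check_pair(x: np.ndarray, xj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if x.shape != xj.shape:
        raise ValueError("input vectors must have the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xj))):
        raise ValueError("non-finite kernel inputs")
    return x, xj


def _matern_poly(t: np.ndarray, n: int) -> np.ndarray:
    """sum_{k=0..n} (n+k)!/(2n)! * C(n,k) * t^(n-k) for t = 2d/sigma."""
    acc = np.zeros_like(t)
    for k in range(n + 1):
        coef = math.factorial(n + k) / math.factorial(2 * n) * math.comb(n, k)
        acc = acc + coef * t ** (n - k)
    return acc


def _eval(spec: KernelSpec, d2: np.ndarray, d1: np.ndarray) -> np.ndarray:
    """Evaluate a stationary family from squared L2 (d2) and L1 (d1) distances."""
    f = spec.family
    if f == "gaussian":
        return np.exp(-d2 / (2 * spec.sigma**2))
    if f == "exponential":
        return np.exp(-np.sqrt(d2) / spec.sigma)
    if f == "laplacian":
        return np.exp(-d1 / spec.sigma)
    if f == "matern":
        d = np.sqrt(d2)
        return np.exp(-d / spec.sigma) * _matern_poly(2 * d / spec.sigma, int(spec.n))
    if f == "periodic":
        d = np.sqrt(d2)
        return np.exp(-2 * np.sin(np.pi * d / spec.p) ** 2 / spec.sigma**2)
    if f == "decaying_periodic":
        d = np.sqrt(d2)
        return np.exp(-d2 / (2 * spec.sigma**2)) * np.exp(
            -2 * np.sin(np.pi * d / spec.p) ** 2 / spec.sigma_p**2
        )
    raise AssertionError(f)


def kernel_value(spec: KernelSpec, x: np.ndarray, xj: np.ndarray) -> float:
    """k(x, x_j) for a single pair of equal-length vectors."""
    x, xj = _check_pair(x, xj)
    if spec.family == "linear":
        return float(x @ xj)
    diff = x - xj
    d2 = np.array(diff @ diff)
    d1 = np.array(np.sum(np.abs(diff)))
    return float(_eval(spec, d2, d1))


def kernel_matrix(spec: KernelSpec, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X[i], X2[j]); symmetric when X2 is X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty input set")
    X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    if X.shape[1] != X2.shape[1]:
        raise ValueError("input vectors must have the same length")
    if spec.family == "linear":
        return X @ X2.T
    # pairwise distances without forming per-pair loops
    sq = (X**2).sum(1)[:, None] + (X2**2).sum(1)[None, :] - 2 * X @ X2.T
    np.maximum(sq, 0.0, out=sq)
    if spec.family == "laplacian":
        d1 = np.abs(X[:, None, :] - X2[None, :, :]).sum(-1)
    else:
        d1 = sq  # unused
    return _eval(spec, sq, d1)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def _gaussian_derivatives(spec, x, xj):
    diff = x - xj
    s2 = spec.sigma**2
    k = math.exp(-(diff @ diff) / (2 * s2))
    grad = -(diff / s2) * k
    hess = k * (np.eye(x.size) / s2 - np.outer(diff, diff) / s2**2)
    return grad, hess


def kernel_derivatives(
    spec: KernelSpec, x: np.ndarray, xj: np.ndarray, fd_step: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """(dk/dx, d^2k/(dx dx_j)) at a pair of input vectors.

    Analytic for the Gaussian kernel; central finite differences (step
    ``fd_step``) for every other family.  Finite differencing a non-smooth
    kernel (Laplacian with a coincident coordinate) triggers a warning.
    """
    x, xj = _check_pair(x, xj)
    if spec.family == "gaussian":
        return _gaussian_derivatives(spec, x, xj)
    if spec.family == "laplacian" and np.any(np.abs(x - xj) < 10 * fd_step):
        warnings.warn(
            "finite differences of the laplacian kernel near a coincident "
            "coordinate are unreliable"
        )
    n = x.size
    h = fd_step
    grad = np.empty(n)
    for a in range(n):
        xp, xm = x.copy(), x.copy()
        xp[a] += h
        xm[a] -= h
        grad[a] = (kernel_value(spec, xp, xj) - kernel_value(spec, xm, xj)) / (2 * h)
    hess = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            vpp = _shifted(spec, x, xj, a, b, h, h)
            vpm = _shifted(spec, x, xj, a, b, h, -h)
            vmp = _shifted(spec, x, xj, a, b, -h, h)
            vmm = _shifted(spec, x, xj, a, b, -h, -h)
            hess[a, b] = (vpp - vpm - vmp + vmm) / (4 * h * h)
    return grad, hess


def _shifted(spec, x, xj, a, b, ha, hb):
    xs, xjs = x.copy(), xj.copy()
    xs[a] += ha
    xjs[b] += hb
    return kernel_value(spec, xs, xjs)
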