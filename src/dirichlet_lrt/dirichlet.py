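"""Dirichlet distribution numerics: density, likelihood, moments, sampling
and maximum-likelihood estimation.

Everything is computed in log space; no product of densities is ever
formed. Maximum-likelihood estimation uses the digamma fixed-point
iteration with a method-of-moments initializer.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = [
    "DirichletParams",
    "FitDiagnostics",
    "FitError",
    "log_multivariate_beta",
    "log_density",
    "log_likelihood",
    "mean",
    "variance",
    "sample",
    "fit_mle",
]

_EULER_GAMMA = float(np.euler_gamma)
_ALPHA0_CAP = 1e8


@dataclasses.dataclass(frozen=True)
class DirichletParams:
    """Positive parameter vector of a Dirichlet distribution.

    ``alpha0`` is the cached component sum.
    """

    alpha: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 2:
            raise ValueError("alpha must be a vector of length >= 2")
        if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
            raise ValueError("all Dirichlet parameters must be finite and > 0")
        object.__setattr__(self, "alpha", alpha)
        if self.class_names is not None:
            names = tuple(self.class_names)
            if len(names) != alpha.size:
                raise ValueError("class_names length must match alpha")
            object.__setattr__(self, "class_names", names)

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def k(self) -> int:
        return int(self.alpha.size)

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha.tolist(), "alpha0": self.alpha0}
        if self.class_names is not None:
            d["class_names"] = list(self.class_names)
        return d


@dataclasses.dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    iterations: int
    final_log_likelihood: float
    init_alpha: np.ndarray

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "iterations": self.iterations,
            "final_log_likelihood": self.final_log_likelihood,
            "init_alpha": np.asarray(self.init_alpha).tolist(),
        }


class FitError(RuntimeError):
    """Maximum-likelihood estimation failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: FitDiagnostics | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


def log_multivariate_beta(alpha: Sequence[float] | np.ndarray) -> float:
    """log B(alpha) = sum log Gamma(alpha_k) - log Gamma(alpha_0).

    Computed entirely via log-gamma so it does not overflow for large
    parameters.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("multivariate beta requires strictly positive entries")
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def _check_simplex(x: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != k:
        raise ValueError(f"dimension mismatch: point has {x.shape[-1]} classes, "
                         f"parameters have {k}")
    if np.any(x <= 0):
        raise ValueError("simplex point must be strictly positive "
                         "(apply preprocessing to remove zeros)")
    if np.any(np.abs(x.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("point does not sum to 1 within 1e-9")
    return x


def log_density(x: Sequence[float] | np.ndarray, params: DirichletParams) -> float:
    """Log Dirichlet density at a single strictly-positive simplex point."""
    x = _check_simplex(np.atleast_1d(np.asarray(x, dtype=float)), params.k)
    return float(-log_multivariate_beta(params.alpha)
                 + ((params.alpha - 1.0) * np.log(x)).sum())


def _group_log_likelihood(samples: np.ndarray, params: DirichletParams) -> float:
    """Sum of log densities of the rows of ``samples`` under one parameter set."""
    samples = _check_simplex(np.atleast_2d(np.asarray(samples, dtype=float)), params.k)
    n = samples.shape[0]
    return float(-n * log_multivariate_beta(params.alpha)
                 + (np.log(samples) @ (params.alpha - 1.0)).sum())


def log_likelihood(groups: Iterable[tuple[np.ndarray, DirichletParams]]) -> float:
    """Joint log-likelihood of per-environment samples under per-environment
    parameters: the sum over environments and samples of the log density."""
    total = 0.0
    count = 0
    for samples, params in groups:
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[0] == 0:
            raise ValueError("empty sample group in log_likelihood")
        total += _group_log_likelihood(samples, params)
        count += 1
    if count == 0:
        raise ValueError("log_likelihood needs at least one group")
    return total


def mean(params: DirichletParams) -> np.ndarray:
    """Componentwise expectation alpha_k / alpha_0 (sums to 1)."""
    return params.alpha / params.alpha0


def variance(params: DirichletParams) -> np.ndarray:
    """Componentwise variance alpha_k (alpha_0 - alpha_k) / (alpha_0^2 (alpha_0 + 1))."""
    a0 = params.alpha0
    return params.alpha * (a0 - params.alpha) / (a0 ** 2 * (a0 + 1.0))


def sample(params: DirichletParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent compositions; rows sum to 1 and are strictly
    positive (zero-valued draws, possible at tiny alpha, are re-drawn)."""
    if n < 1:
        raise ValueError("need n >= 1 draws")
    out = rng.dirichlet(params.alpha, size=n)
    # Gamma draws can underflow to exactly 0 for small alpha; re-draw those rows.
    for _ in range(100):
        bad = np.any(out <= 0, axis=1)
        if not bad.any():
            break
        out[bad] = rng.dirichlet(params.alpha, size=int(bad.sum()))
    else:
        raise FitError("could not draw strictly positive compositions")
    return out


@njit(cache=True)
def _psi(x: float) -> float:
    """Scalar digamma for x > 0: recurrence up to x >= 6, then the
    asymptotic series (~1e-14 relative accuracy)."""
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    y = 1.0 / x
    y2 = y * y
    return r + math.log(x) - 0.5 * y - y2 * (
        1.0 / 12.0 - y2 * (1.0 / 120.0 - y2 * (1.0 / 252.0 - y2 * (
            1.0 / 240.0 - y2 / 132.0)))
    )


@njit(cache=True)
def _psi1(x: float) -> float:
    """Scalar trigamma for x > 0 (recurrence + asymptotic series)."""
    r = 0.0
    while x < 6.0:
        r += 1.0 / (x * x)
        x += 1.0
    y = 1.0 / x
    y2 = y * y
    return r + y + 0.5 * y2 + y * y2 * (
        1.0 / 6.0 - y2 * (1.0 / 30.0 - y2 * (1.0 / 42.0 - y2 / 30.0))
    )


@njit(cache=True)
def _inv_psi(y: float) -> float:
    """Newton inversion of the digamma function (5 iterations from the
    standard piecewise initializer; ~14 significant digits)."""
    if y >= -2.22:
        x = math.exp(y) + 0.5
    else:
        x = -1.0 / (y + _EULER_GAMMA)
    for _ in range(5):
        x -= (_psi(x) - y) / _psi1(x)
    return x


@njit(cache=True)
def _fixed_point_loop(
    log_xbar: np.ndarray,
    alpha_init: np.ndarray,
    tol: float,
    max_iter: int,
    cap: float,
) -> tuple[np.ndarray, int, bool, bool]:
    """Digamma fixed-point iteration alpha_k <- psi_inv(psi(alpha_0) + mean
    log x_k); returns (alpha, iterations, converged, diverged)."""
    k = log_xbar.size
    alpha = alpha_init.copy()
    it = 0
    for it in range(1, max_iter + 1):
        psi_a0 = _psi(alpha.sum())
        new = np.empty(k)
        delta = 0.0
        for j in range(k):
            new[j] = _inv_psi(psi_a0 + log_xbar[j])
            d = abs(new[j] - alpha[j]) / alpha[j]
            if d > delta:
                delta = d
        if new.sum() > cap:
            return new, it, False, True
        alpha = new
        if delta < tol:
            return alpha, it, True, False
    return alpha, it, False, False


def _moment_init(samples: np.ndarray) -> np.ndarray:
    """Method-of-moments initializer from the first class's mean/variance;
    falls back to all-ones when that variance is degenerate."""
    mbar = samples.mean(axis=0)
    v1 = samples[:, 0].var(ddof=0)
    if v1 <= 0 or mbar[0] <= 0 or mbar[0] >= 1:
        return np.ones(samples.shape[1])
    a0 = mbar[0] * (1.0 - mbar[0]) / v1 - 1.0
    if a0 <= 0:
        return np.ones(samples.shape[1])
    return np.maximum(mbar * a0, 1e-8)


def fit_mle(
    samples: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 20_000,
    class_names: tuple[str, ...] | None = None,
) -> tuple[DirichletParams, FitDiagnostics]:
    """Maximum-likelihood Dirichlet fit by digamma fixed-point iteration.

    Iterates ``alpha_k <- psi_inv(psi(alpha_0) + mean_j log x_jk)`` from a
    method-of-moments start until ``max |delta alpha_k| / alpha_k < tol``.

    Raises
    ------
    FitError
        On non-convergence within ``max_iter``, or when alpha_0 exceeds a
        divergence cap of 1e8 (near-identical compositions make the
        likelihood unbounded).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, k = samples.shape
    if n < 2:
        raise ValueError("need at least 2 samples to fit a Dirichlet")
    if k < 2:
        raise ValueError("need at least 2 classes")
    if np.any(samples <= 0):
        raise ValueError("samples must be strictly positive on the simplex")
    if np.all(samples.std(axis=0) < 1e-12):
        raise FitError(
            "degenerate data: compositions (near-)identical, MLE unbounded"
        )

    log_xbar = np.log(samples).mean(axis=0)
    init_alpha = _moment_init(samples)

    def ll(a: np.ndarray) -> float:
        return float(n * (gammaln(a.sum()) - gammaln(a).sum())
                     + n * ((a - 1.0) * log_xbar).sum())

    alpha, it, converged, diverged = _fixed_point_loop(
        log_xbar, init_alpha, tol, max_iter, _ALPHA0_CAP
    )
    if diverged:
        raise FitError(
            "degenerate data: compositions (near-)identical, MLE unbounded",
            FitDiagnostics(False, it, ll(alpha), init_alpha),
        )
    diagnostics = FitDiagnostics(converged, it, ll(alpha), init_alpha)
    if not converged:
        raise FitError(
            f"Dirichlet MLE did not converge after {max_iter} iterations",
            diagnostics,
        )
    return DirichletParams(alpha, class_names=class_names), diagnostics
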