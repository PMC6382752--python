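"""Likelihood-ratio test for equality of Dirichlet compositions across
environments.

The statistic is D = -2 log(L0 / L1), where L0 is the likelihood maximized
with one shared parameter vector for all environments and L1 maximizes an
independent vector per environment. Under the null, D is asymptotically
chi-squared with (m - 1) K degrees of freedom; for small samples an
empirical null built by permuting environment labels is preferred.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.stats import chi2

from .composition import CompositionTable, normalize
from .dirichlet import DirichletParams, FitError, fit_mle, log_likelihood
from .preprocess import FilterReport, FilterSpec, filter_classes

__all__ = [
    "LRTResult",
    "lrt_statistic",
    "chi2_pvalue",
    "randomization_pvalue",
    "recommend_method",
    "dirichlet_lrt",
]

logger = logging.getLogger(__name__)

_CLAMP_TOL = 1e-9
DEFAULT_N_TRIALS = 5000


@dataclasses.dataclass(frozen=True)
class LRTResult:
    """Outcome of the composition likelihood-ratio test."""

    D: float
    df: int
    logL0: float
    logL1: float
    alpha_null: DirichletParams
    alpha_alt: dict[str, DirichletParams]
    method_used: str
    p_chi2: float | None = None
    p_rand: float | None = None
    n_rand_trials: int = 0
    n_exceed: int = 0
    filter_report: FilterReport | None = None
    m: int = 0
    K: int = 0
    group_sizes: dict[str, int] | None = None
    seed: int | None = None

    @property
    def p_rand_display(self) -> str | None:
        """Randomization p-value as reported: a bound when no permuted
        statistic reached the observed one."""
        if self.p_rand is None:
            return None
        if self.n_exceed == 0 and self.n_rand_trials > 0:
            return f"p < {1.0 / self.n_rand_trials:g}"
        return f"{self.p_rand:g}"

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "df": self.df,
            "logL0": self.logL0,
            "logL1": self.logL1,
            "p_chi2": self.p_chi2,
            "p_rand": self.p_rand,
            "p_rand_display": self.p_rand_display,
            "n_rand_trials": self.n_rand_trials,
            "n_exceed": self.n_exceed,
            "method_used": self.method_used,
            "m": self.m,
            "K": self.K,
            "group_sizes": self.group_sizes,
            "seed": self.seed,
            "alpha_null": self.alpha_null.to_dict(),
            "alpha_alt": {env: p.to_dict() for env, p in self.alpha_alt.items()},
            "filter_report": (
                self.filter_report.to_dict() if self.filter_report else None
            ),
        }

    def summary(self) -> str:
        lines = [
            "Dirichlet likelihood-ratio test",
            f"  environments (m): {self.m}   classes after filter (K): {self.K}",
            f"  group sizes: {self.group_sizes}",
            f"  D = {self.D:.6g}   df = {self.df}",
            f"  log L0 = {self.logL0:.6g}   log L1 = {self.logL1:.6g}",
            f"  method: {self.method_used}",
        ]
        if self.p_chi2 is not None:
            lines.append(f"  chi-squared p-value: {self.p_chi2:.6g}")
        if self.p_rand is not None:
            lines.append(
                f"  randomization p-value: {self.p_rand_display} "
                f"({self.n_exceed}/{self.n_rand_trials} exceedances)"
            )
        if self.seed is not None:
            lines.append(f"  seed: {self.seed}")
        if self.filter_report is not None:
            lines.append("  " + self.filter_report.summary().replace("\n", "\n  "))
        return "\n".join(lines)


def _check_testable(table: CompositionTable) -> None:
    if table.n_environments < 2:
        raise ValueError("need at least 2 environments to test")
    for env, n_i in table.group_sizes.items():
        if n_i < 2:
            raise ValueError(
                f"environment {env!r} has {n_i} sample; likelihood unbounded "
                "for singleton groups"
            )
    if np.any(table.values <= 0):
        raise ValueError("table contains zero entries; apply class filtering first")


def lrt_statistic(
    table: CompositionTable,
) -> tuple[float, float, float, DirichletParams, dict[str, DirichletParams]]:
    """Compute D with the pooled (null) and per-environment (alternative)
    maximum-likelihood fits.

    Returns ``(D, logL0, logL1, alpha_null, alpha_alt)``; D is clamped to 0
    when a tiny negative value (< 1e-9 in magnitude) arises from floating
    point.
    """
    _check_testable(table)
    names = table.class_names

    alpha_null, _ = fit_mle(table.values, class_names=names)
    logL0 = log_likelihood([(table.values, alpha_null)])

    alpha_alt: dict[str, DirichletParams] = {}
    logL1 = 0.0
    for env in table.env_labels:
        group = table.group_values(env)
        try:
            params, diag = fit_mle(group, class_names=names)
        except FitError as exc:
            raise FitError(
                f"fit failed for environment {env!r}: {exc}", exc.diagnostics
            ) from exc
        alpha_alt[env] = params
        logL1 += log_likelihood([(group, params)])

    D = 2.0 * (logL1 - logL0)
    if D < 0:
        if D < -_CLAMP_TOL:
            raise FitError(
                f"negative statistic D={D}: alternative fit worse than null; "
                "optimizer failure"
            )
        D = 0.0
    return D, logL0, logL1, alpha_null, alpha_alt


def chi2_pvalue(D: float, m: int, K: int) -> float:
    """Upper-tail chi-squared probability of D at (m - 1) K degrees of
    freedom; survival-function evaluation keeps magnitudes down to ~1e-300
    representable."""
    if D < 0:
        raise ValueError("D must be non-negative")
    df = (m - 1) * K
    if m < 2 or K < 2 or df < 1:
        raise ValueError(f"invalid degrees of freedom (m={m}, K={K})")
    return float(chi2.sf(D, df))


def recommend_method(n_total: int, m: int, K: int, ratio: float = 2.0) -> str:
    """Advise chi2 vs randomization from the sample count and the
    dimensionality m*K: randomization when n < ratio * m * K (boundary
    inclusive for chi2). Advisory only."""
    if min(n_total, m, K) < 1 or ratio <= 0:
        raise ValueError("arguments must be positive")
    return "randomization" if n_total < ratio * m * K else "chi2"


def randomization_pvalue(
    table: CompositionTable,
    n_trials: int = DEFAULT_N_TRIALS,
    rng: np.random.Generator | None = None,
    D_obs: float | None = None,
) -> tuple[float, int]:
    """Empirical p-value by permuting environment labels.

    Each trial permutes the label vector uniformly at random (preserving
    group sizes), recomputes D, and counts trials with D_rand >= D_obs.
    Trials where the MLE fails are re-drawn and logged. When no trial
    reaches D_obs the stored p-value is 0 and reports state p < 1/n_trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng or np.random.default_rng()
    _check_testable(table)
    if D_obs is None:
        D_obs, *_ = lrt_statistic(table)

    labels = np.array(table.environments)
    n_exceed = 0
    n_failed = 0
    done = 0
    max_failures = 10 * n_trials
    while done < n_trials:
        permuted = rng.permutation(labels)
        try:
            D_rand, *_ = lrt_statistic(table.with_environments(permuted))
        except FitError:
            n_failed += 1
            if n_failed > max_failures:
                raise FitError(
                    "randomization aborted: too many failed permutation fits"
                )
            continue
        if D_rand >= D_obs:
            n_exceed += 1
        done += 1
    if n_failed:
        logger.info("randomization: %d failed trials re-drawn", n_failed)
    return n_exceed / n_trials, n_exceed


def dirichlet_lrt(
    table: CompositionTable,
    spec: FilterSpec | None = None,
    method: str = "auto",
    n_trials: int = DEFAULT_N_TRIALS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LRTResult:
    """Full pipeline: normalize, filter classes, fit, and compute p-values.

    ``method`` is one of ``chi2``, ``randomization``, ``both`` or ``auto``
    (advisory choice from the n vs m*K geometry).
    """
    if method not in {"chi2", "randomization", "both", "auto"}:
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = normalize(table)
    filtered, report = filter_classes(table, spec)

    D, logL0, logL1, alpha_null, alpha_alt = lrt_statistic(filtered)
    m, K = filtered.n_environments, filtered.n_classes
    df = (m - 1) * K

    if method == "auto":
        method_used = recommend_method(filtered.n_samples, m, K)
        logger.info(
            "auto method selection: n=%d, mK=%d -> %s",
            filtered.n_samples, m * K, method_used,
        )
    else:
        method_used = method

    p_chi2 = p_rand = None
    n_exceed = 0
    n_done = 0
    if method_used in {"chi2", "both"}:
        p_chi2 = chi2_pvalue(D, m, K)
    if method_used in {"randomization", "both"}:
        p_rand, n_exceed = randomization_pvalue(filtered, n_trials, rng, D_obs=D)
        n_done = n_trials

    return LRTResult(
        D=D,
        df=df,
        logL0=logL0,
        logL1=logL1,
        alpha_null=alpha_null,
        alpha_alt=alpha_alt,
        method_used=method_used,
        p_chi2=p_chi2,
        p_rand=p_rand,
        n_rand_trials=n_done,
        n_exceed=n_exceed,
        filter_report=report,
        m=m,
        K=K,
        group_sizes=filtered.group_sizes,
        seed=seed,
    )
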