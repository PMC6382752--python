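"""Power estimation for future experiments by simulation from the fitted
alternative model.

The per-environment maximum-likelihood parameters fitted to observed data
are taken as the truth; synthetic experiments with n replicates per
environment are simulated and put through the likelihood-ratio test, and
the rejection proportion estimates the power. This procedure is
computationally expensive, especially with the randomization inner test.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .composition import CompositionTable, normalize
from .dirichlet import DirichletParams, FitError, fit_mle, sample
from .lrt import chi2_pvalue, lrt_statistic, randomization_pvalue
from .preprocess import FilterSpec, filter_classes

__all__ = ["PowerResult", "power_estimate", "power_curve"]

logger = logging.getLogger(__name__)

DEFAULT_N_SIMS = 500


@dataclasses.dataclass(frozen=True)
class PowerResult:
    group_sizes: tuple[int, ...]
    power: tuple[float, ...]
    n_sims: int
    significance: float
    method: str
    alpha_tilde: dict[str, DirichletParams]
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "group_sizes": list(self.group_sizes),
            "power": list(self.power),
            "n_sims": self.n_sims,
            "significance": self.significance,
            "method": self.method,
            "seed": self.seed,
            "alpha_tilde": {env: p.to_dict() for env, p in self.alpha_tilde.items()},
        }

    def summary(self) -> str:
        lines = [
            "Power estimates by simulation from the fitted alternative model",
            f"  inner test: {self.method}   significance: {self.significance}"
            f"   simulations per group size: {self.n_sims}",
        ]
        for n, p in zip(self.group_sizes, self.power):
            lines.append(f"  n = {n:>4d} per environment -> power {p:.3f}")
        return "\n".join(lines)


def _simulate_table(
    alpha_tilde: Sequence[DirichletParams], n: int, rng: np.random.Generator
) -> CompositionTable:
    envs: list[str] = []
    blocks: list[np.ndarray] = []
    for i, params in enumerate(alpha_tilde):
        blocks.append(sample(params, n, rng))
        envs.extend([f"env{i + 1}"] * n)
    values = np.vstack(blocks)
    return CompositionTable(
        sample_ids=tuple(f"s{i + 1}" for i in range(values.shape[0])),
        class_names=tuple(f"c{k + 1}" for k in range(values.shape[1])),
        environments=tuple(envs),
        values=values,
        is_normalized=True,
    )


def power_estimate(
    alpha_tilde: Sequence[DirichletParams],
    n: int,
    n_sims: int = DEFAULT_N_SIMS,
    significance: float = 0.05,
    method: str = "chi2",
    rng: np.random.Generator | None = None,
    sim_seeds: Sequence[np.random.SeedSequence] | None = None,
    n_rand_trials: int = 200,
) -> float:
    """Estimated power of an experiment with ``n`` replicates per
    environment when the per-environment truth is ``alpha_tilde``.

    ``sim_seeds`` (one SeedSequence per simulation) pairs draws across
    different ``n`` so power curves are monotone up to shared noise.
    Simulations whose inner fit fails are re-drawn; more than 10% failures
    aborts.
    """
    alpha_tilde = list(alpha_tilde)
    if len(alpha_tilde) < 2:
        raise ValueError("need at least 2 environments")
    if n < 2:
        raise ValueError("need n >= 2 replicates per environment")
    if not (0.0 < significance <= 1.0):
        raise ValueError("significance must lie in (0, 1]")
    if method not in {"chi2", "randomization"}:
        raise ValueError(f"unknown method {method!r}")
    if sim_seeds is not None and len(sim_seeds) < n_sims:
        raise ValueError("need one seed sequence per simulation")
    if sim_seeds is None and rng is None:
        rng = np.random.default_rng()

    m = len(alpha_tilde)
    K = alpha_tilde[0].k
    successes = 0
    failures = 0
    max_failures = max(1, n_sims // 10)
    for j in range(n_sims):
        sim_rng = (
            np.random.default_rng(sim_seeds[j]) if sim_seeds is not None else rng
        )
        while True:
            try:
                sim = _simulate_table(alpha_tilde, n, sim_rng)
                D, *_ = lrt_statistic(sim)
                if method == "chi2":
                    p = chi2_pvalue(D, m, K)
                else:
                    p, _ = randomization_pvalue(sim, n_rand_trials, sim_rng, D_obs=D)
                break
            except FitError:
                failures += 1
                if failures > max_failures:
                    raise FitError(
                        f"power simulation: more than 10% of draws failed "
                        f"({failures} failures)"
                    )
        if p < significance:
            successes += 1
    if failures:
        logger.info("power simulation: %d failed draws re-drawn", failures)
    return successes / n_sims


def power_curve(
    table: CompositionTable,
    spec: FilterSpec | None = None,
    n_range: Sequence[int] = (),
    n_sims: int = DEFAULT_N_SIMS,
    significance: float = 0.05,
    method: str = "chi2",
    seed: int | None = None,
    n_rand_trials: int = 200,
) -> PowerResult:
    """Fit the alternative model to observed data and estimate power over a
    range of per-environment group sizes (paired simulations across n)."""
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range must contain at least one group size")
    table = normalize(table)
    filtered, _ = filter_classes(table, spec)
    names = filtered.class_names
    alpha_tilde = {
        env: fit_mle(filtered.group_values(env), class_names=names)[0]
        for env in filtered.env_labels
    }
    params = [alpha_tilde[env] for env in filtered.env_labels]

    sim_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    power = tuple(
        power_estimate(
            params,
            n,
            n_sims=n_sims,
            significance=significance,
            method=method,
            sim_seeds=sim_seeds,
            n_rand_trials=n_rand_trials,
        )
        for n in n_range
    )
    return PowerResult(
        group_sizes=tuple(n_range),
        power=power,
        n_sims=n_sims,
        significance=significance,
        method=method,
        alpha_tilde=alpha_tilde,
        seed=seed,
    )
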