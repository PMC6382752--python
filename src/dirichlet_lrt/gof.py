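"""Simulation-based goodness-of-fit test for the Dirichlet model.

T0 is the log-likelihood of the fitted parameters on the observed data.
N datasets with identical geometry (K, m, n_i) are simulated from the fit
and scored at the SAME parameters (no refitting); the proportion of
simulated log-likelihoods below T0 is the p-value. A small p-value means
the observed data are less likely than typical draws, i.e. a poor fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .composition import CompositionTable
from .dirichlet import DirichletParams, fit_mle, log_likelihood, sample

__all__ = ["GOFResult", "gof_test"]

DEFAULT_N_SIMS = 10_000


@dataclasses.dataclass(frozen=True)
class GOFResult:
    T0: float
    T_sim: np.ndarray
    p_gof: float
    n_sims: int
    model_used: str
    alpha_fit: dict[str, DirichletParams]
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "T0": self.T0,
            "p_gof": self.p_gof,
            "n_sims": self.n_sims,
            "model_used": self.model_used,
            "seed": self.seed,
            "alpha_fit": {env: p.to_dict() for env, p in self.alpha_fit.items()},
            "T_sim_mean": float(np.mean(self.T_sim)),
            "T_sim_quantiles": {
                q: float(np.quantile(self.T_sim, float(q)))
                for q in ("0.01", "0.25", "0.5", "0.75", "0.99")
            },
        }

    def summary(self) -> str:
        return "\n".join([
            "Dirichlet goodness-of-fit test",
            f"  model: {self.model_used}   simulations: {self.n_sims}",
            f"  observed log-likelihood T0 = {self.T0:.6g}",
            f"  simulated log-likelihood median = {float(np.median(self.T_sim)):.6g}",
            f"  p-value (proportion of simulations below T0): {self.p_gof:.6g}",
            "  note: a SMALL p-value indicates a poor fit",
        ])


def gof_test(
    table: CompositionTable,
    model: str = "alt_fit",
    n_sims: int = DEFAULT_N_SIMS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> GOFResult:
    """Run the goodness-of-fit simulation on a filtered table.

    ``model="alt_fit"`` fits one parameter vector per environment (the
    model used by the significance test under the alternative);
    ``model="null_fit"`` fits a single pooled vector.
    """
    if model not in {"alt_fit", "null_fit"}:
        raise ValueError(f"unknown model {model!r}")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable p-value")
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.any(table.values <= 0):
        raise ValueError("table contains zero entries; apply class filtering first")

    names = table.class_names
    if model == "alt_fit":
        groups = [(env, table.group_values(env)) for env in table.env_labels]
        fits = {env: fit_mle(g, class_names=names)[0] for env, g in groups}
        group_fits = [(g, fits[env]) for env, g in groups]
    else:
        pooled, _ = fit_mle(table.values, class_names=names)
        fits = {"pooled": pooled}
        group_fits = [
            (table.group_values(env), pooled) for env in table.env_labels
        ]

    T0 = log_likelihood(group_fits)

    sizes = [g.shape[0] for g, _ in group_fits]
    params = [p for _, p in group_fits]
    T_sim = np.empty(n_sims)
    for j in range(n_sims):
        T_sim[j] = log_likelihood(
            (sample(p, n_i, rng), p) for n_i, p in zip(sizes, params)
        )
    p_gof = float(np.count_nonzero(T_sim < T0)) / n_sims

    return GOFResult(
        T0=T0,
        T_sim=T_sim,
        p_gof=p_gof,
        n_sims=n_sims,
        model_used=model,
        alpha_fit=fits,
        seed=seed,
    )
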