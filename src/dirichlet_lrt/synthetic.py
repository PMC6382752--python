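"""Scenario generator producing composition tables with known Dirichlet
structure, so every stage of the pipeline is testable without external
data.

A :class:`Scenario` describes the geometry (m environments with n_i
samples each), the per-environment parameter vectors (identical vectors
give a null scenario), an optional mixture contamination used to exercise
goodness-of-fit misfit detection, and an optional injection of rare /
zero-bearing classes used to exercise the class filter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import CompositionTable
from .dirichlet import DirichletParams, sample

__all__ = ["RareClass", "Contamination", "Scenario", "generate", "paper_like_geometries"]


@dataclasses.dataclass(frozen=True)
class RareClass:
    """A class spliced into generated tables at a fixed small proportion,
    optionally zeroed in specific samples (indices into the full table)."""

    name: str
    proportion: float
    zero_samples: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.proportion < 1.0):
            raise ValueError("rare-class proportion must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class Contamination:
    """Mixture misfit: each sample is drawn from the scenario's alphas with
    probability 1 - weight and from these alternatives otherwise."""

    alphas: tuple[tuple[float, ...], ...]
    weight: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.weight < 1.0):
            raise ValueError("contamination weight must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class Scenario:
    n_i: tuple[int, ...]
    alphas: tuple[tuple[float, ...], ...]
    seed: int = 0
    contamination: Contamination | None = None
    rare_classes: tuple[RareClass, ...] = ()
    env_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.n_i) != len(self.alphas):
            raise ValueError("need one alpha vector per environment")
        if len(self.n_i) < 1 or any(n < 1 for n in self.n_i):
            raise ValueError("every environment needs at least one sample")
        k = len(self.alphas[0])
        if k <= 2:
            raise ValueError("alpha vectors must have length K > 2")
        for a in self.alphas:
            if len(a) != k:
                raise ValueError("all alpha vectors must share one length")
            if any(x <= 0 for x in a):
                raise ValueError("alpha entries must be strictly positive")
        if self.contamination is not None:
            if len(self.contamination.alphas) != len(self.alphas):
                raise ValueError("contamination needs one alpha vector per environment")
        if self.env_names is not None and len(self.env_names) != len(self.n_i):
            raise ValueError("env_names must match the number of environments")

    @property
    def m(self) -> int:
        return len(self.n_i)

    @property
    def k(self) -> int:
        return len(self.alphas[0])

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "n_i": list(self.n_i),
            "alphas": [list(a) for a in self.alphas],
            "seed": self.seed,
        }
        if self.contamination is not None:
            d["contamination"] = {
                "alphas": [list(a) for a in self.contamination.alphas],
                "weight": self.contamination.weight,
            }
        if self.rare_classes:
            d["rare_classes"] = [
                {
                    "name": rc.name,
                    "proportion": rc.proportion,
                    "zero_samples": list(rc.zero_samples),
                }
                for rc in self.rare_classes
            ]
        if self.env_names is not None:
            d["env_names"] = list(self.env_names)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Scenario":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        d = json.loads(source)
        contamination = None
        if "contamination" in d:
            contamination = Contamination(
                alphas=tuple(tuple(a) for a in d["contamination"]["alphas"]),
                weight=d["contamination"].get("weight", 0.5),
            )
        rare = tuple(
            RareClass(
                name=rc["name"],
                proportion=rc["proportion"],
                zero_samples=tuple(rc.get("zero_samples", ())),
            )
            for rc in d.get("rare_classes", ())
        )
        return cls(
            n_i=tuple(d["n_i"]),
            alphas=tuple(tuple(a) for a in d["alphas"]),
            seed=d.get("seed", 0),
            contamination=contamination,
            rare_classes=rare,
            env_names=tuple(d["env_names"]) if "env_names" in d else None,
        )


def generate(scenario: Scenario) -> CompositionTable:
    """Draw a composition table from the scenario (deterministic under its
    seed). Rare classes are spliced in after drawing and rows renormalized
    so the output stays on the simplex."""
    rng = np.random.default_rng(scenario.seed)
    env_names = scenario.env_names or tuple(
        f"env{i + 1}" for i in range(scenario.m)
    )

    blocks: list[np.ndarray] = []
    envs: list[str] = []
    for i, (n_i, alpha) in enumerate(zip(scenario.n_i, scenario.alphas)):
        params = DirichletParams(np.asarray(alpha, dtype=float))
        block = sample(params, n_i, rng)
        if scenario.contamination is not None:
            alt = DirichletParams(
                np.asarray(scenario.contamination.alphas[i], dtype=float)
            )
            pick = rng.random(n_i) < scenario.contamination.weight
            if pick.any():
                block[pick] = sample(alt, int(pick.sum()), rng)
        blocks.append(block)
        envs.extend([env_names[i]] * n_i)
    values = np.vstack(blocks)
    class_names = [f"class{k + 1}" for k in range(scenario.k)]

    for rc in scenario.rare_classes:
        col = np.full(values.shape[0], rc.proportion)
        col[list(rc.zero_samples)] = 0.0
        values = np.column_stack([values, col])
        class_names.append(rc.name)
    values /= values.sum(axis=1, keepdims=True)

    return CompositionTable(
        sample_ids=tuple(f"s{i + 1}" for i in range(values.shape[0])),
        class_names=tuple(class_names),
        environments=tuple(envs),
        values=values,
        is_normalized=True,
    )


def paper_like_geometries(seed: int = 0) -> list[Scenario]:
    """Scenarios mimicking the shapes of published composition studies
    (synthetic placeholder parameters; only the geometry n_i x K matters):

    - 8 environments x 3 samples, K=8   (soil resistance-gene classes, n=24, mK=64)
    - 8 environments x ~3 samples, K=12 (soil phyla, one sample missing, n=23, mK=96)
    - 3 environments x 4 samples, K=9   (seasonal resistance-gene classes, n=12, mK=27)
    - 3 environments x 4 samples, K=5   (seasonal phyla, n=12, mK=15)
    - 2 environments of 226 and 128, K=21 (two-site phyla, n=354, mK=42)
    """
    def alphas(m: int, k: int, scale: float, rng: np.random.Generator):
        base = rng.uniform(0.5, 3.0, size=k) * scale
        return tuple(tuple(base * rng.uniform(0.8, 1.25, size=k)) for _ in range(m))

    rng = np.random.default_rng(seed)
    shapes = [
        ((3,) * 8, 8, 10.0),
        ((3,) * 7 + (2,), 12, 10.0),
        ((4,) * 3, 9, 8.0),
        ((4,) * 3, 5, 8.0),
        ((226, 128), 21, 15.0),
    ]
    out = []
    for i, (n_i, k, scale) in enumerate(shapes):
        out.append(
            Scenario(n_i=n_i, alphas=alphas(len(n_i), k, scale, rng), seed=seed + i)
        )
    return out
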