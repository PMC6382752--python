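import numpy as np
import pytest

from dirichlet_lrt import CompositionTable, DirichletParams, sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(values, environments, sample_ids=None, class_names=None,
               is_normalized=False):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return CompositionTable(
        sample_ids=sample_ids or tuple(f"s{i+1}" for i in range(n)),
        class_names=class_names or tuple(f"c{j+1}" for j in range(k)),
        environments=tuple(environments),
        values=values,
        is_normalized=is_normalized,
    )


def dirichlet_table(alphas, n_i, seed, env_names=None):
    """n_i[i] draws from Dirichlet(alphas[i]) per environment, as a table."""
    rng = np.random.default_rng(seed)
    blocks, envs = [], []
    env_names = env_names or [f"env{i+1}" for i in range(len(alphas))]
    for name, alpha, n in zip(env_names, alphas, n_i):
        blocks.append(sample(DirichletParams(np.asarray(alpha, float)), n, rng))
        envs.extend([name] * n)
    return make_table(np.vstack(blocks), envs, is_normalized=True)


@pytest.fixture
def two_env_table():
    """m=2, K=3, n_i=10 each, moderately separated parameters."""
    return dirichlet_table([(2, 5, 3), (5, 2, 3)], [10, 10], seed=7)


@pytest.fixture
def null_table():
    """m=3, n_i=4, K=5, one shared parameter vector (null scenario)."""
    return dirichlet_table([(2, 5, 3, 4, 6)] * 3, [4, 4, 4], seed=11)
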