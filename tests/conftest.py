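import numpy as np
import pandas as pd
import pytest

from magfred.redundancy import AbundanceProfile, TraitDistanceMatrix


def brute_force_rao(p: np.ndarray, d: np.ndarray) -> float:
    """Independent O(n^2) oracle for Rao's quadratic entropy."""
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            total += p[i] * p[j] * d[i][j]
    return total


def brute_force_cliffs(x, y) -> float:
    """Independent pair-enumeration oracle for Cliff's delta."""
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))


def random_community(rng: np.random.Generator, n: int):
    """Random profile + unit-scaled distance matrix over n MAGs."""
    p = rng.dirichlet(np.ones(n))
    while (p <= 0).any():
        p = rng.dirichlet(np.ones(n))
    d = rng.uniform(0, 1, size=(n, n))
    d = np.triu(d, 1)
    d = d + d.T
    ids = tuple(f"m{i}" for i in range(n))
    return AbundanceProfile(ids, p / p.sum()), TraitDistanceMatrix(ids, d)


@pytest.fixture
def guild_table():
    """2 guilds x 2 members, one-hot guild centroids: closed-form FRed = 1/3."""
    rows = {
        "g0m0": [1.0, 0.0],
        "g0m1": [1.0, 0.0],
        "g1m0": [0.0, 1.0],
        "g1m1": [0.0, 1.0],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["tA", "tB"])


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "total_genes": [2000, 2000, 1800, 2200],
            "completeness": [80.0, 80.0, 90.0, 95.0],
            "contamination": [1.0, 2.0, 0.5, 3.0],
            "order": ["OrdA", "OrdA", "OrdB", "OrdB"],
            "fraction": ["PA", "FL", "PA", "FL"],
        },
        index=pd.Index(["g0m0", "g0m1", "g1m0", "g1m1"], name="mag_id"),
    )
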