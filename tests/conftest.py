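import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ExpressionMatrix,
    SimulationConfig,
    TraitTable,
    WGCNA,
    simulate_expression,
)

STUDY_POWER = 9  # soft threshold used for the planted-recovery runs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """10 genes x 12 samples of random log-scale expression."""
    values = rng.normal(7.0, 1.0, size=(10, 12))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:02d}" for i in range(10)],
            columns=[f"s{i:02d}" for i in range(12)],
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default planted dataset: (config, expression, traits, truth)."""
    cfg = SimulationConfig()
    expr, traits, truth = simulate_expression(cfg)
    return cfg, expr, traits, truth


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Full analysis of the default planted dataset at the study power."""
    _, expr, traits, truth = default_sim
    res = WGCNA(expr, traits, power=STUDY_POWER, primary_trait="grade").fit()
    return res, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def naive_upgma_heights(d: np.ndarray) -> list:
    """O(n^3) UPGMA returning sorted merge heights."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def naive_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap with endpoint-excluding sum."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, m] * a[m, j] for m in range(n) if m not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Definitional Pearson correlation."""
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))
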