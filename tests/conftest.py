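import numpy as np
import pandas as pd
import pytest

from mirsig import synthetic
from mirsig.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """A 2,000-gene mimic experiment with 5 planted clusters of 120 genes,
    no distortion — shared by clustering/differential/signature tests."""
    config = synthetic.SyntheticConfig(
        n_genes=2000, clusters=synthetic.default_clusters(120), seed=11
    )
    return synthetic.generate_dataset(config)


@pytest.fixture()
def tiny_matrix():
    """4 genes x 6 samples, two groups, hand-checkable."""
    values = pd.DataFrame(
        np.arange(24, dtype=float).reshape(4, 6) + 1.0,
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = pd.Series(
        ["ctrl"] * 3 + ["treat"] * 3, index=values.columns, name="group"
    )
    return ExpressionMatrix(values, groups)


def upgma_oracle_heights(D: np.ndarray) -> list[float]:
    """Brute-force O(n^3) UPGMA: inter-cluster distance is the mean of all
    original pairwise distances. Returns merge heights in merge order."""
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights: list[float] = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(float(d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights
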