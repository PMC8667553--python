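import numpy as np
import pytest

from pathlasso.data import (
    PathwayCollection,
    SurvivalDataset,
    build_latent_design,
    standardize,
)


def random_survival(rng, n, m, censor_frac=0.3, ties=False):
    """Small random survival instance for oracle comparisons."""
    X = rng.normal(size=(n, m))
    time = rng.exponential(1.0, n)
    if ties:
        time = np.round(time, 1)
    event = (rng.random(n) >= censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return X, time, event


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(42)
    n, m = 40, 6
    X, time, event = random_survival(rng, n, m)
    return SurvivalDataset(
        expression=X,
        gene_ids=[f"g{i}" for i in range(m)],
        time=time,
        event=event,
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def overlapping_pathways():
    return PathwayCollection({
        "P1": ["g0", "g1", "g2"],
        "P2": ["g2", "g3"],
        "P3": ["g4", "g5"],
    })


@pytest.fixture
def small_design(small_dataset, overlapping_pathways):
    std, _ = standardize(small_dataset)
    return build_latent_design(std, overlapping_pathways)
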