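import numpy as np
import pytest

import redunet as r


def ring_correlation_matrix(n: int = 41, seed: int = 0) -> np.ndarray:
    """Correlation-like matrix whose strongest edges form a spanning ring.

    With n = 41 the 5% edge quota is round(0.05 * 820) = 41 = n, so the
    whole ring fits inside the sparsest default density.
    """
    rng = np.random.default_rng(seed)
    corr = rng.uniform(0.05, 0.45, size=(n, n))
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    for i in range(n):
        j = (i + 1) % n
        corr[i, j] = corr[j, i] = 0.9
    return corr


def star_correlation_matrix(n: int = 41, seed: int = 1) -> np.ndarray:
    """Correlation-like matrix whose strongest edges form a hub star."""
    rng = np.random.default_rng(seed)
    corr = rng.uniform(0.05, 0.45, size=(n, n))
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    for j in range(1, n):
        corr[0, j] = corr[j, 0] = 0.9
    return corr


@pytest.fixture(scope="session")
def ring_matrix() -> np.ndarray:
    return ring_correlation_matrix()


@pytest.fixture(scope="session")
def star_matrix() -> np.ndarray:
    return star_correlation_matrix()


@pytest.fixture(scope="session")
def small_cohort() -> r.SyntheticCohort:
    """A 24-subject cohort small enough for end-to-end tests."""
    return r.gen_cohort(n_subjects=24, n_regions=16, n_volumes=204, seed=11)


@pytest.fixture(scope="session")
def fast_config() -> r.PipelineConfig:
    """Pipeline config with a coarse window step to keep tests quick."""
    return r.PipelineConfig(step_volumes=10)
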