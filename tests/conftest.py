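import numpy as np
import pytest

from mirnapanel import CovariateTable, ExpressionDataset
from mirnapanel.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_fit():
    """One shared scaled-down fit of the tiny-k3 fixture (expensive)."""
    from mirnapanel import McmcSettings, fit_hierarchical
    dataset, cov, truth = make_fixture("tiny-k3", I=200)
    draws = fit_hierarchical(dataset, cov, settings=McmcSettings(
        chains=2, iterations=900, burn_in=300, thin=1, seed=5))
    return dataset, cov, truth, draws


@pytest.fixture
def toy_k2():
    """Hand-sized K=2, I=3 dataset with one missing covariate of each kind."""
    rng = np.random.default_rng(99)
    y = rng.normal(size=9)
    dataset = ExpressionDataset(
        y=y,
        mirna_index=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0]),
        subject_index=np.array([0, 0, 0, 0, 1, 1, 2, 2, 2]),
        replicate=np.array([1, 1, 2, 2, 1, 1, 1, 1, 2]),
        mirna_names=["mirA", "mirB"], subject_ids=["s1", "s2", "s3"])
    cov = CovariateTable(
        disease=np.array([0.0, 1.0, np.nan]),
        age_std=np.array([0.3, np.nan, -1.2]),
        bw_std=np.array([np.nan, 0.8, 0.1]))
    return dataset, cov
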