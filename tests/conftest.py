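import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fedrisk.data_model import FeatureMatrix, SiteDataset, split_site


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_feature_matrix(rng, n_persons=8, n_covs=6, density=0.4) -> FeatureMatrix:
    mask = rng.random((n_persons, n_covs)) < density
    # long CSV carries no empty rows/columns (absent pairs are zeros), so
    # guarantee every person and covariate has at least one nonzero cell
    for i in range(n_persons):
        mask[i, i % n_covs] = True
    for j in range(n_covs):
        mask[j % n_persons, j] = True
    vals = np.where(mask, np.round(rng.random((n_persons, n_covs)) * 5 + 1, 3), 0.0)
    persons = np.array([f"p{i}" for i in range(n_persons)], dtype=object)
    covs = np.array([f"c{j}" for j in range(n_covs)], dtype=object)
    return FeatureMatrix(persons, covs, sp.csr_matrix(vals))


@pytest.fixture
def small_matrix(rng):
    return random_feature_matrix(rng, n_persons=20)


def make_site(
    n=60, d=5, seed=0, site_id="s", case_frac=0.3, informative=True
) -> SiteDataset:
    """Small dense-ish site where feature 0 carries the outcome signal."""
    r = np.random.default_rng(seed)
    X = (r.random((n, d)) < 0.4).astype(float)
    if informative:
        logits = -1.5 + 3.0 * X[:, 0]
        y = (r.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    else:
        y = (r.random(n) < case_frac).astype(int)
    persons = np.array([f"{site_id}_p{i}" for i in range(n)], dtype=object)
    covs = np.array([f"c{j}" for j in range(d)], dtype=object)
    fm = FeatureMatrix(persons, covs, sp.csr_matrix(X))
    labels = pd.Series(y, index=persons.astype(str))
    return split_site(fm, labels, seed=seed, site_id=site_id)


@pytest.fixture
def small_site():
    return make_site(n=120, seed=3)
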