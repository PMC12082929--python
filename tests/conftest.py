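import numpy as np
import pandas as pd
import pytest

import csfnet as cn
from csfnet import synthetic as syn


def make_blocks(sizes, n_samples, rho, seed, n_noise=0):
    """Latent-factor block matrix: within-block correlation ~ rho, zero
    across blocks; optional iid noise rows.  Returns (DataFrame, labels)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, s in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((s, n_samples)))
        labels += [b + 1] * s
    if n_noise:
        rows.append(rng.standard_normal((n_noise, n_samples)))
        labels += [0] * n_noise
    X = np.vstack(rows)
    ids = [f"X{i:05d}|G{i:04d}" for i in range(X.shape[0])]
    cols = [f"s{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(X, index=ids, columns=cols), np.array(labels)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact single-center cohort with planted effects (5 modules)."""
    params = syn.TruthParams(
        n_proteins=400, n_modules=5, max_module_size=60, min_module_size=20,
        subthreshold_module_size=10, group_effects=syn.default_group_effects(),
    )
    matrix, traits, truth = cn.generate_cohort(cn.single_center_design(), params, seed=101)
    return matrix, traits, truth


@pytest.fixture(scope="session")
def small_network(small_cohort):
    matrix, traits, truth = small_cohort
    net = cn.build_network(matrix, cn.NetworkParams())
    return net, truth
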