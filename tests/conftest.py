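import numpy as np
import pandas as pd
import pytest

from ctxprog import CohortConfig, generate_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas60():
    return generate_atlas(60, seed=1)


@pytest.fixture(scope="session")
def clean_cohort(atlas60):
    """Small homogeneous-noise cohort for unit tests of individual stages."""
    cfg = CohortConfig(missing_frac=0.1, frac_noisy_genes=0.0)
    donors, truth = generate_cohort(atlas60, 4, 300, cfg, seed=1)
    return donors, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, regions=None, genes=None):
    """Wrap a raw array as a RegionGeneMatrix with default ids."""
    from ctxprog import RegionGeneMatrix

    values = np.asarray(values, float)
    regions = regions or [f"R{i:02d}" for i in range(values.shape[0])]
    genes = genes or [f"G{j:03d}" for j in range(values.shape[1])]
    return RegionGeneMatrix(pd.DataFrame(values, index=regions, columns=genes))
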