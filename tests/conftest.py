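import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_marginal_data():
    """One strong-effect training/test replicate pair (six SNPs OR 1.8, p=10)."""
    import grsforge as gf

    design = gf.scenario1_design(1.8, 4, 500, seed=11, n_replicates=2)
    train, test = gf.generate_replicates(design)
    return design, train, test
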