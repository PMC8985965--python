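import numpy as np
import pytest

from injuryprofiles import default_template, sample_cohort


@pytest.fixture(scope="session")
def block_cohort():
    """Small well-separated 3-class cohort (block-diagonal template)."""
    cfg = default_template(n_classes=3, n_items=12, n=400, seed=11)
    return cfg, sample_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort_small():
    """Default 7-profile template at reduced cohort size."""
    cfg = default_template(n=800, seed=3)
    return cfg, sample_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20220406)
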