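import numpy as np
import pytest

import metabofp as m
from metabofp.synthetic import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-group cohort with the default male signature planted."""
    cfg = CohortConfig(
        n_per_group_per_sex={("dn2PD", "M"): 20, ("CTR", "M"): 20,
                             ("dn2PD", "F"): 15, ("CTR", "F"): 15},
        effect_table=m.synthetic.study_effect_table(),
        seed=42,
    )
    table, meta = m.simulate_cohort(cfg)
    return table, meta


@pytest.fixture(scope="session")
def training_buckets():
    """Study-sized training cohort bucketed from simulated spectra."""
    table, meta = m.simulate_cohort(m.study_config("training", seed=7))
    spectra = m.simulate_spectra(table, noise_sd=5e-4, seed=8)
    bm = m.build_bucket_matrix(spectra, meta)
    return table, bm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
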