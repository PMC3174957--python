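import numpy as np
import pytest

from eqtlink.synthetic_data import SimConfig, generate_study_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study bundle with one strong planted cis+disease SNP."""
    cfg = SimConfig(
        n_snps=60,
        n_genes=6,
        study_sizes=[(300, 300), (200, 200)],
        replication_study_sizes=[(400, 400), (300, 300)],
        cis_effect_sizes={"rs00015": 1.5},
        disease_log_odds={"rs00015": 0.5},
        maf_range=(0.2, 0.5),
        master_seed=11,
    )
    return generate_study_bundle(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """A bundle with no planted effects (type-I-error fodder)."""
    cfg = SimConfig(
        n_snps=60,
        n_genes=6,
        study_sizes=[(200, 200)],
        replication_study_sizes=[(200, 200), (200, 200)],
        master_seed=7,
    )
    return generate_study_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
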