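import numpy as np
import pytest
from hypothesis import settings

from hlamatch.hla_model import load_bundled_matrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hlamatch.synthetic_data import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def blosum50():
    return load_bundled_matrix("blosum50")


@pytest.fixture(scope="session")
def pmbec():
    return load_bundled_matrix("pmbec_synthetic")


@pytest.fixture(scope="session")
def small_dataset():
    """A 25-couple null cohort with one unassayed allele per locus."""
    cfg = SyntheticCohortConfig(
        seed=7,
        n_rm=13,
        n_control=12,
        alleles_per_locus=8,
        n_peptides=30,
        n_unassayed_alleles=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_dataset():
    """A 30-couple near-separable cohort (large effect size, no label noise)."""
    cfg = SyntheticCohortConfig(
        seed=11,
        n_rm=15,
        n_control=15,
        alleles_per_locus=8,
        n_peptides=30,
        effect_size=10.0,
        label_noise=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
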