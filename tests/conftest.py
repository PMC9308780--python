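import pytest

from credyn.synthetic_data import SimConfig, make_ground_truth


SMALL_SIM = dict(
    chrom_length_bp=4_000_000,
    n_epi_cres=60,
    n_pre_cres_early=60,
    n_pre_cres_late=30,
    n_background_peaks=60,
    n_decoy_genes=4,
    n_stable_genes=200,
)


@pytest.fixture
def small_config():
    return SimConfig(seed=1, **SMALL_SIM)


@pytest.fixture
def small_truth(small_config):
    return make_ground_truth(small_config)
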