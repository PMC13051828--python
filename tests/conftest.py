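import pytest

from cernanet.config import PAPER_SCALE, SyntheticConfig
from cernanet.synthetic import write_bundle

# small but structurally complete planted configuration for fast unit tests
SMALL_CONFIG = SyntheticConfig(
    n_genes=500,
    n_mirnas=60,
    n_kd_up=20,
    n_kd_down=60,
    n_ovx_up=70,
    n_ovx_down=50,
    n_candidates=10,
    n_target_binders=30,
    n_driver_binders=25,
    n_intersection=15,
    n_expressed=8,
    n_mt_edges=20,
    n_samples_n=2,
    n_samples_mm=20,
    n_samples_pcl=5,
    cohort_n=100,
    seed=3,
)

# the tiny instance whose interaction table can be checked by exhaustive
# enumeration: 5 miRNAs, 3 candidates, intersection 2, 4 counted edges
TINY_CONFIG = SyntheticConfig(
    n_genes=50,
    n_mirnas=5,
    n_kd_up=2,
    n_kd_down=5,
    n_ovx_up=5,
    n_ovx_down=2,
    n_candidates=3,
    n_target_binders=4,
    n_driver_binders=3,
    n_intersection=2,
    n_expressed=2,
    n_mt_edges=4,
    n_samples_n=2,
    n_samples_mm=8,
    n_samples_pcl=2,
    cohort_n=20,
    seed=11,
)


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    """Full synthetic input bundle at the published scale (written once)."""
    outdir = tmp_path_factory.mktemp("paper_bundle")
    return write_bundle(PAPER_SCALE, outdir)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def tiny_config():
    return TINY_CONFIG
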