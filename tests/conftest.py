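import numpy as np
import pytest

from clonotrx.barcode_quant import BarcodeLibrarySpec
from clonotrx.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture
def library() -> BarcodeLibrarySpec:
    return BarcodeLibrarySpec("TCGATTAGCGCA", "GCTAATGCGTCA", 6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort shared by read-level round-trip tests."""
    cfg = SimulationConfig(n_clones=10, n_mice=1, read_depth=5000, n_cells=300,
                           n_genes=80, n_mito_genes=5, frac_high_mito=0.1,
                           bridge_coverage=0.5, bridge_multimap_rate=0.05, seed=7)
    return simulate_cohort(cfg)
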