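import numpy as np
import pytest

from bulkscan.simulate import SimConfig, simulate_dataset

SMALL_CHROMS = {"chrA": 2_000_000, "chrB": 1_500_000}


@pytest.fixture
def small_config() -> SimConfig:
    """Small two-chromosome design with one strong QTL, for fast tests."""
    return SimConfig(
        n_f2=80,
        bulk_size=20,
        chrom_lengths=dict(SMALL_CHROMS),
        snp_density=30.0,
        qtl=(("chrA", 800_000, 0.2, 0.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One simulated dataset written to disk (VCF/GFF3/TSV/JSON), shared."""
    config = SimConfig(
        n_f2=80,
        bulk_size=20,
        chrom_lengths=dict(SMALL_CHROMS),
        snp_density=30.0,
        qtl=(("chrA", 800_000, 0.2, 0.0),),
        seed=11,
    )
    out = tmp_path_factory.mktemp("sim")
    paths = simulate_dataset(config, out)
    return config, paths


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
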