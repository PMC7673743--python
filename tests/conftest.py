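import numpy as np
import pytest

from damidreg.fragments import GATCFragmentMap
from damidreg.genome import GenomeModel
from damidreg.pipeline import PipelineConfig, run_pipeline
from damidreg.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run at the default study conditions."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic genome for unit-level truth checks."""
    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length_bp=120_000,
        n_genes=40,
        n_peaks_shared=4,
        n_peaks_gained=2,
        n_peaks_lost=2,
        read_depth=200_000,
        regulon_size=8,
        regulon_core_size=6,
        n_accessible_genes=10,
        n_background_pres=30,
    )
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture
def toy_genome():
    """Single 20-bp chromosome with GATC at 2 and 10."""
    return GenomeModel(chromosomes=[("chrA", 20, "AAGATCAAAAGATCAAAAAA")])


@pytest.fixture
def unit_fragmap():
    """1000 unit-length fragments on one synthetic chromosome."""
    return GATCFragmentMap(
        ["chr1"], {"chr1": 1000}, {"chr1": np.arange(0, 1001, dtype=np.int64)}
    )
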