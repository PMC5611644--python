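import numpy as np
import pandas as pd
import pytest

from methdyn.io import StageMethylome, METHYLOME_COLUMNS
from methdyn.simulate import (
    SimulationConfig,
    plant_truth,
    random_planted_dmrs,
    simulate_genome,
    simulate_stage,
)


def make_methylome(rows, stage=""):
    """Build a StageMethylome from (chrom, pos, strand, context, n_meth, n_unmeth) tuples."""
    df = pd.DataFrame(rows, columns=list(METHYLOME_COLUMNS))
    return StageMethylome(df, stage=stage)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=1,
        chrom_length=300_000,
        n_tes=40,
        n_genes=40,
        n_saturated_sites=60,
        n_sirna_reads=20_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    return plant_truth(small_config, small_genome)


@pytest.fixture(scope="session")
def small_stages(small_config, small_genome, small_truth):
    return {
        s: simulate_stage(small_config, s, small_genome, small_truth)
        for s in small_config.stage_profiles
    }
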