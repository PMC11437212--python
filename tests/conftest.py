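import numpy as np
import pytest

import hetmap as hm
from hetmap import simulate


@pytest.fixture(scope="session")
def toy_genome():
    return hm.GenomeSpec.from_lengths(
        {"1": 80_000_000, "2": 40_000_000, "3": 20_000_000, "4": 10_000_000},
        macro_names={"1", "2"},
    )


@pytest.fixture(scope="session")
def toy_panel(toy_genome):
    genome, panel, genes = simulate.simulate_genome(
        toy_genome, markers_per_chrom=300, seed=11
    )
    return genome, panel, genes


@pytest.fixture(scope="session")
def toy_dataset(toy_panel):
    """Error-free simulated pedigree dataset with known truth."""
    genome, panel, genes = toy_panel
    model = simulate.default_crossover_model(genome)
    ped = simulate.PedigreeSpec(
        n_families=12,
        offspring_per_family=4,
        fraction_with_grandparents=0.25,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
    )
    gd, truth = simulate.simulate_pedigree_genotypes(genome, panel, model, ped, seed=5)
    return genome, panel, genes, model, gd, truth
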