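import numpy as np
import pytest

from stratsim import (
    AncestralModel,
    PhenotypeModel,
    draw_population_freqs,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_pair():
    """400-SNP, 4-chromosome frequency pair shared by cheap tests."""
    model = AncestralModel(num_snps=400, num_chromosomes=4, seed=17)
    return draw_population_freqs(model)


@pytest.fixture(scope="session")
def small_labels():
    return np.array(["pop1"] * 30 + ["pop2"] * 40)


@pytest.fixture(scope="session")
def small_dataset(small_pair, small_labels):
    return simulate_genotypes(small_pair, small_labels, 0.0, seed=17)


@pytest.fixture(scope="session")
def small_phenotype(small_dataset):
    return simulate_phenotype(
        small_dataset, PhenotypeModel(divergence_delta=1.5), seed=23)
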