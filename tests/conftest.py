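import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from mirdeg.containers import ExperimentDesign
from mirdeg.synthio import generate_reference, plant_truth


@pytest.fixture(scope="session")
def small_ref():
    """60 transcripts / 20 miRNAs with planted sites and 2 novel hairpins."""
    return generate_reference(60, 20, seed=11, n_novel_hairpins=2)


@pytest.fixture(scope="session")
def small_truth(small_ref):
    return plant_truth(small_ref, n_modules=8, seed=11)


@pytest.fixture(scope="session")
def one_genotype_design():
    return ExperimentDesign(genotypes=("TL",), timepoints=(5,), replicates=3)


@pytest.fixture(scope="session")
def two_genotype_design():
    return ExperimentDesign(genotypes=("TL", "SL"), timepoints=(5,), replicates=3)
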