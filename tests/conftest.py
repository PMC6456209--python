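import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from its2morph.alignment import encode
from its2morph.synthetic import StructureTemplate, generate_species_set


@pytest.fixture(scope="session")
def template():
    return StructureTemplate()


@pytest.fixture(scope="session")
def three_species_set():
    """3 species x 3 records, 2 planted CBCs per species, no indels."""
    return generate_species_set(
        n_species=3, n_per_species=3, cbc_between=2, hemicbc_within=1,
        indel_rate=0.0, seed=101,
    )


@pytest.fixture(scope="session")
def truth_encoded(three_species_set):
    """Records of the synthetic set encoded with their true structures."""
    seqs, truth = three_species_set
    encs = []
    for rec in seqs:
        lo, hi = truth.its2_span[rec.id]
        encs.append(encode(rec.sequence[lo - 1 : hi], truth.dotbrackets[rec.id], rec.id))
    return encs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
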