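import numpy as np
import pandas as pd
import pytest

from xenosplit import (
    ProteinRecord,
    Proteome,
    QuantMatrix,
    classify_peptides,
    combine_proteomes,
    digest_proteome,
)
from xenosplit.digest import DigestParams


@pytest.fixture
def toy_proteomes():
    """Minimal two-species pair: one shared tryptic peptide (AAAK), one
    discriminating peptide per species (DDDR human, EEER mouse)."""
    human = Proteome("human", [ProteinRecord("H1", "human", "", "AAAKDDDR")])
    mouse = Proteome("mouse", [ProteinRecord("M1", "mouse", "", "AAAKEEER")])
    return human, mouse


@pytest.fixture
def toy_index(toy_proteomes):
    human, mouse = toy_proteomes
    combined = combine_proteomes([human, mouse])
    params = DigestParams(max_missed_cleavages=0, min_length=4, max_length=52)
    return classify_peptides(digest_proteome(combined, params))


@pytest.fixture
def toy_quant(toy_index):
    rows = {
        ("DDDR", 2): [10.0, 12.0, 11.0, 13.0],
        ("EEER", 2): [20.0, 21.0, 19.0, 22.0],
        ("AAAK", 2): [5.0, 6.0, 5.5, 6.5],
    }
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=["s1", "s2", "s3", "s4"]
    )
    values.index = pd.MultiIndex.from_tuples(
        values.index, names=["modified_sequence", "charge"]
    )
    groups = {"s1": "group1", "s2": "group1", "s3": "group2", "s4": "group2"}
    return QuantMatrix(values=values, sample_groups=groups)


def random_protein(rng: np.random.Generator, length: int) -> str:
    alphabet = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(alphabet[rng.integers(0, 20, size=length)])
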