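import numpy as np
import pytest

from litcooc.ner import Dictionary
from litcooc.synthetic_data import (
    GeneratorConfig,
    gen_corpus,
    gen_dictionary,
    gen_truth,
)


@pytest.fixture(scope="session")
def small_dictionary() -> Dictionary:
    """Handcrafted dictionary: genes, a disease chain, a compartment diamond.

    Disease ontology chain: t1d (4) -> dm (5) -> gmd (6, root).
    Compartment diamond: leafc (12) -> {midA (10), midB (11)} -> croot (13).
    Name "shared" is deliberately gene/compartment ambiguous; "common" is a
    stop word.
    """
    entries = {
        1: ("GENE:0001", "gene"),
        2: ("GENE:0002", "gene"),
        3: ("GENE:0003", "gene"),
        4: ("DOID:t1d", "disease"),
        5: ("DOID:dm", "disease"),
        6: ("DOID:gmd", "disease"),
        10: ("GO:midA", "compartment"),
        11: ("GO:midB", "compartment"),
        12: ("GO:leafc", "compartment"),
        13: ("GO:croot", "compartment"),
        20: ("AUX:x", "tissue"),
    }
    names = {
        "tp53": {1},
        "mdm2": {2},
        "insulin": {3},
        "insulin receptor": {2},
        "t1d": {4},
        "diabetes": {5},
        "gmd": {6},
        "nucleolus": {12},
        "shared": {1, 12},
        "common": {3},
        "liver": {20},
        "paralogx": {1, 3},
    }
    parents = {4: {5}, 5: {6}, 12: {10, 11}, 10: {13}, 11: {13}}
    return Dictionary(entries, names, stopwords={"common"}, parents=parents)


@pytest.fixture(scope="session")
def tiny_generated():
    """Small noiseless generated corpus with its dictionary and truth."""
    cfg = GeneratorConfig(
        n_documents=120,
        years=(2000, 2008),
        seed=5,
        noise_rates={},
        n_positive_pairs=8,
        effect_size_range=(0.01, 0.05),
    )
    tables = gen_dictionary(cfg)
    truth = gen_truth(cfg, tables)
    corpus = gen_corpus(cfg, tables, truth)
    return cfg, tables, truth, corpus


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
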