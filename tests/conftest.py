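import numpy as np
import pytest

from lexner.corpus_io import EntityDictionary, LabeledSentence, RadicalTable
from lexner.model import DualBranchNER, ModelConfig
from lexner.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small deterministic corpus shared across unit tests."""
    return generate(SynthConfig(n_train=40, n_dev=10, n_test=10, n_unlabeled=15,
                                seed=11))


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """Untrained desk-scale model over the tiny corpus."""
    ds = tiny_dataset
    return DualBranchNER.from_corpus(ds.train, ds.dictionary, ds.radical_table,
                                     ModelConfig(), seed=3)


@pytest.fixture
def toy_dictionary():
    d = EntityDictionary()
    d.add(("A", "B"), "Dis")
    d.add(("A", "B", "C"), "Dru")
    return d


@pytest.fixture
def toy_sentences():
    return [
        LabeledSentence(chars=list("XABCY"), labels=["O", "B-Dis", "I-Dis", "I-Dis", "O"]),
        LabeledSentence(chars=list("AB"), labels=["B-Dru", "I-Dru"]),
    ]
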