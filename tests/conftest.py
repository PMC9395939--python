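import numpy as np
import pytest

from dialogi import synthetic_data as synth
from dialogi import textproc
from dialogi.concept_spaces import DenseSpace


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(n_docs=80, vocab_size=500, n_disease_terms=40,
                             n_chem_terms=40, signal_strength=0.8, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return synth.gen_documents(small_config)


@pytest.fixture(scope="session")
def small_annotations(small_corpus):
    return synth.gen_annotations(small_corpus)


@pytest.fixture(scope="session")
def small_processed(small_corpus, small_annotations):
    anns = textproc.parse_pubtator(small_annotations)
    return textproc.process_documents(small_corpus.documents, anns)


def random_space(n_terms: int, dim: int, seed: int, prefix: str = "T") -> DenseSpace:
    rng = np.random.default_rng(seed)
    terms = [f"{prefix}{i:04d}" for i in range(n_terms)]
    return DenseSpace(terms=terms, matrix=rng.standard_normal((n_terms, dim)),
                      provenance="svd")


def noisy_copy(space: DenseSpace, sigma: float, seed: int) -> DenseSpace:
    rng = np.random.default_rng(seed)
    return DenseSpace(terms=list(space.terms),
                      matrix=space.matrix + sigma * rng.standard_normal(space.matrix.shape),
                      provenance="svd")
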