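"""End-to-end convenience wrappers over the pipeline stages.

These exist so that tests, the acceptance report and scripts can run the
whole chain (synthetic corpus -> processed documents -> concept spaces ->
feature vectors) with a couple of calls; each step is just the public API of
the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic_data as synth
from . import textproc
from .concept_spaces import (DenseSpace, corpus_from_associations, embed_pipeline,
                             reduce_svd, tfidf)
from .features import batch_featurize
from .textproc import AnnotatedDocument


@dataclass
class PreparedCorpus:
    corpus: synth.SynthCorpus
    documents: list[AnnotatedDocument]
    texts: list[list[str]]          # processed token sequences (plain mode)
    labels: np.ndarray
    features: np.ndarray | None = None
    coverage: dict | None = None


def prepare_corpus(config: synth.SynthConfig,
                   manifest: synth.Manifest | None = None,
                   mode: str = "plain") -> PreparedCorpus:
    """Generate documents + annotations and run the textproc stage."""
    corpus = synth.gen_documents(config, manifest)
    annotations = textproc.parse_pubtator(synth.gen_annotations(corpus))
    documents = textproc.process_documents(corpus.documents, annotations)
    texts = [textproc.export_processed(d, mode) for d in documents]
    labels = np.array([d.label for d in documents], dtype=np.float64)
    return PreparedCorpus(corpus=corpus, documents=documents, texts=texts, labels=labels)


def synthetic_concept_spaces(config: synth.SynthConfig, seed: int = 0,
                             n_partners: int = 400, method: str = "svd",
                             ) -> dict[str, DenseSpace]:
    """Disease and chemical spaces learnt from block-structured association
    tables that share term ids (and blocks) with the document generator.

    ``method='svd'`` stops after TF-IDF+SVD (fast); ``'node2vec'`` runs the
    full network/node2vec chain.
    """
    spaces = {}
    plan = (("disease", config.n_disease_terms, synth.DISEASE_ID_BASE, seed + 21),
            ("chemical", config.n_chem_terms, synth.CHEMICAL_ID_BASE, seed + 22))
    for category, n_terms, id_base, table_seed in plan:
        tables, _ = synth.gen_association_tables(
            n_terms, n_partners, n_blocks=config.n_blocks, seed=table_seed,
            id_base=id_base)
        corpus = corpus_from_associations(tables[0])
        if method == "node2vec":
            spaces[category] = embed_pipeline(corpus, n_pairs=20_000, seed=table_seed)
        else:
            spaces[category] = reduce_svd(tfidf(corpus), target_variance=0.9)
    return spaces


def attach_features(prepared: PreparedCorpus, disease_space: DenseSpace,
                    chemical_space: DenseSpace) -> PreparedCorpus:
    matrix, _ids, report = batch_featurize(prepared.documents, disease_space,
                                           chemical_space)
    prepared.features = matrix
    prepared.coverage = report
    return prepared
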