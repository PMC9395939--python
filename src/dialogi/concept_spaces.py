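"""Concept-embedding pipeline: corpus -> TF-IDF -> truncated SVD ->
empirical-null similarity network -> node2vec.

TF-IDF dialect: document frequency is binary (presence), words kept when
``min_df <= df <= max_df_frac * n_terms`` (filtering happens before
weighting), tf is the raw count and idf = ln(n/df) + 1, with no row
normalization.  Terms whose vectors become all-zero after filtering are
purged.  Explained variance for the (uncentred) SVD is s_i^2 / sum s_j^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .node2vec import Node2VecParams, node2vec

logger = logging.getLogger(__name__)


class EmptySpaceError(ValueError):
    """Every word (or term) was filtered away."""


@dataclass
class ConceptCorpus:
    documents: dict[str, list[str]]   # term id -> bag of words (with multiplicity)
    source_kind: str                  # "hierarchy" | "association"

    def __post_init__(self) -> None:
        for term, words in self.documents.items():
            if any(not w for w in words):
                raise ValueError(f"term {term}: empty word in document")


@dataclass
class SparseSpace:
    terms: list[str]
    vocab: list[str]
    matrix: sp.csr_matrix  # terms x vocab, TF-IDF weights


@dataclass
class DenseSpace:
    terms: list[str]
    matrix: np.ndarray     # terms x k
    explained_variance: float | None = None
    provenance: str = "svd"

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.terms)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def get(self, term: str) -> np.ndarray | None:
        i = self._index.get(term)
        return None if i is None else self.matrix[i]


@dataclass
class SimilarityNetwork:
    nodes: list[str]
    edges: dict[tuple[str, str], float]   # (u, v) with u < v -> -log10(p)
    null_sample: np.ndarray = field(repr=False)
    seed: int | None = None

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


def corpus_from_hierarchy(hierarchy: pd.DataFrame) -> ConceptCorpus:
    """One word per tree-number prefix: ``c1.c2.c3`` contributes ``c1``,
    ``c1.c2`` and ``c1.c2.c3``; all of a term's tree numbers pool with
    multiplicity."""
    documents: dict[str, list[str]] = {}
    for row in hierarchy.itertuples(index=False):
        tree = str(row.tree_number).strip()
        if not tree:
            continue
        parts = tree.split(".")
        words = [".".join(parts[: i + 1]) for i in range(len(parts))]
        documents.setdefault(str(row.term_id), []).extend(words)
    empty = [t for t, words in documents.items() if not words]
    for t in empty:
        logger.warning("term %s has no tree numbers; excluded", t)
        del documents[t]
    return ConceptCorpus(documents=documents, source_kind="hierarchy")


def corpus_from_associations(associations: pd.DataFrame) -> ConceptCorpus:
    """Each term's document is its multiset of interaction partners."""
    documents: dict[str, list[str]] = {}
    for row in associations.itertuples(index=False):
        documents.setdefault(str(row.term_id), []).append(str(row.partner_id))
    return ConceptCorpus(documents=documents, source_kind="association")


def tfidf(corpus: ConceptCorpus, min_df: int = 5, max_df_frac: float = 0.8) -> SparseSpace:
    if not corpus.documents:
        raise EmptySpaceError("empty corpus")
    terms = sorted(corpus.documents)
    n = len(terms)
    df_counts: dict[str, int] = {}
    for term in terms:
        for w in set(corpus.documents[term]):
            df_counts[w] = df_counts.get(w, 0) + 1
    max_df = max_df_frac * n
    vocab = sorted(w for w, df in df_counts.items() if min_df <= df <= max_df)
    if not vocab:
        raise EmptySpaceError(
            f"all {len(df_counts)} words fell outside df range [{min_df}, {max_df:.1f}]")
    col = {w: j for j, w in enumerate(vocab)}
    idf = np.array([math.log(n / df_counts[w]) + 1.0 for w in vocab])

    rows, cols, vals = [], [], []
    for i, term in enumerate(terms):
        counts: dict[str, int] = {}
        for w in corpus.documents[term]:
            if w in col:
                counts[w] = counts.get(w, 0) + 1
        for w, c in counts.items():
            rows.append(i)
            cols.append(col[w])
            vals.append(c * idf[col[w]])
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, len(vocab)))

    keep = np.asarray((matrix != 0).sum(axis=1)).ravel() > 0
    if not keep.all():
        purged = [t for t, k in zip(terms, keep) if not k]
        logger.warning("purged %d all-zero terms: %s", len(purged), purged[:5])
        matrix = matrix[keep]
        terms = [t for t, k in zip(terms, keep) if k]
    if not terms:
        raise EmptySpaceError("every term became a zero vector")
    return SparseSpace(terms=terms, vocab=vocab, matrix=matrix)


def _svd_flip(components: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude loading of each component positive."""
    signs = np.sign(components[np.argmax(np.abs(components), axis=0), range(components.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def reduce_svd(space: SparseSpace | DenseSpace, target_variance: float = 0.9,
               n_components: int | None = None) -> DenseSpace:
    """Project terms onto the top singular directions.

    When ``n_components`` is given it wins; otherwise k is the smallest
    component count whose cumulative explained-variance ratio reaches
    ``target_variance`` (capped at the matrix rank, with a warning if even
    full rank falls short).
    """
    if n_components is None and not 0.0 < target_variance < 1.0:
        raise ValueError(f"target_variance must be in (0,1), got {target_variance}")
    matrix = space.matrix.toarray() if sp.issparse(space.matrix) else np.asarray(space.matrix)
    matrix = matrix.astype(np.float64)
    u, s, _vt = scipy.linalg.svd(matrix, full_matrices=False)
    tol = s.max(initial=0.0) * max(matrix.shape) * np.finfo(np.float64).eps
    rank = int((s > tol).sum())
    if rank == 0:
        raise EmptySpaceError("zero matrix has no SVD reduction")
    total = float((s[:rank] ** 2).sum())
    evr = np.cumsum(s[:rank] ** 2) / total
    if n_components is not None:
        k = min(n_components, rank)
    else:
        reached = np.nonzero(evr >= target_variance - 1e-12)[0]
        if len(reached):
            k = int(reached[0]) + 1
        else:
            logger.warning("full rank %d explains only %.3f < %.3f variance",
                           rank, evr[-1], target_variance)
            k = rank
    signs = _svd_flip(u[:, :k])
    reduced = u[:, :k] * s[:k] * signs
    return DenseSpace(terms=list(space.terms), matrix=reduced,
                      explained_variance=float(evr[k - 1]), provenance="svd")


def _unit_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(matrix, axis=1)
    nonzero = norms > 0
    unit = np.zeros_like(matrix, dtype=np.float64)
    unit[nonzero] = matrix[nonzero] / norms[nonzero, None]
    return unit, nonzero


def empirical_null(space: DenseSpace | SparseSpace, n_pairs: int = 100_000,
                   seed: int = 0) -> np.ndarray:
    """Sorted cosine similarities of ``n_pairs`` random distinct-term pairs
    drawn with replacement (zero-norm terms excluded from the pool)."""
    matrix = space.matrix.toarray() if sp.issparse(space.matrix) else np.asarray(space.matrix)
    unit, nonzero = _unit_rows(matrix.astype(np.float64))
    pool = np.nonzero(nonzero)[0]
    if len(pool) < len(matrix):
        logger.warning("excluded %d zero-norm terms from null sampling",
                       len(matrix) - len(pool))
    if len(pool) < 2:
        raise ValueError("need at least 2 nonzero terms to sample a null")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, len(pool), size=n_pairs)
    b = rng.integers(0, len(pool), size=n_pairs)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, len(pool), size=int(clash.sum()))
        clash = a == b
    cos = np.einsum("ij,ij->i", unit[pool[a]], unit[pool[b]])
    # rounding makes p-value ranks robust to BLAS summation-order jitter
    return np.sort(np.round(cos, 12))


def pvalue(cos_sim: float | np.ndarray, null: np.ndarray) -> float | np.ndarray:
    """Empirical upper-tail p with add-one smoothing:
    ``(#{null >= cos} + 1) / (N + 1)``."""
    n = len(null)
    at_least = n - np.searchsorted(null, cos_sim, side="left")
    return (at_least + 1) / (n + 1)


def build_network(space: DenseSpace, null: np.ndarray, n_neighbors: int = 100,
                  weight_floor: float = 2.0, forced_k: int = 3,
                  seed: int | None = None) -> SimilarityNetwork:
    """Similarity network over a term space.

    Candidate edges are the union of each term's ``n_neighbors`` top-cosine
    partners (self excluded; cosine ties broken by ascending term id); edge
    weight is -log10 of the empirical p-value.  Edges with weight <=
    ``weight_floor`` are pruned, except that every term keeps its ``forced_k``
    nearest partners from the original cosine ranking; an edge survives if
    either endpoint demands it.
    """
    n = len(space.terms)
    if n <= forced_k:
        raise ValueError(f"need more than forced_k={forced_k} terms, got {n}")
    unit, _ = _unit_rows(np.asarray(space.matrix, dtype=np.float64))
    cos = unit @ unit.T
    np.fill_diagonal(cos, -np.inf)

    edges: dict[tuple[str, str], float] = {}
    for i in range(n):
        # sort by descending cosine, ties by ascending term id
        ranked = sorted(range(n), key=lambda j: (-cos[i, j], space.terms[j]))
        ranked = [j for j in ranked if j != i][:n_neighbors]
        for pos, j in enumerate(ranked):
            w = float(-np.log10(pvalue(round(cos[i, j], 12), null)))
            if pos < forced_k or w > weight_floor:
                u, v = sorted((space.terms[i], space.terms[j]))
                edges[(u, v)] = max(edges.get((u, v), -np.inf), w)
    return SimilarityNetwork(nodes=list(space.terms), edges=edges,
                             null_sample=null, seed=seed)


def node2vec_embed(network: SimilarityNetwork, dim: int = 128, seed: int = 0,
                   params: Node2VecParams | None = None) -> DenseSpace:
    """Weighted-walk skip-gram embedding of the similarity network."""
    if not network.nodes:
        raise ValueError("empty network")
    params = params or Node2VecParams(dim=dim)
    nodes, matrix = node2vec(network.nodes, network.edges, params=params, seed=seed)
    return DenseSpace(terms=nodes, matrix=matrix, provenance="node2vec")


def embed_pipeline(corpus: ConceptCorpus, min_df: int = 5, max_df_frac: float = 0.8,
                   target_variance: float = 0.9, dim: int = 128, n_pairs: int = 100_000,
                   n_neighbors: int = 100, seed: int = 0) -> DenseSpace:
    """Full chain: TF-IDF -> SVD -> empirical-null network -> node2vec."""
    sparse = tfidf(corpus, min_df=min_df, max_df_frac=max_df_frac)
    reduced = reduce_svd(sparse, target_variance=target_variance)
    null = empirical_null(reduced, n_pairs=n_pairs, seed=seed)
    network = build_network(reduced, null, n_neighbors=n_neighbors, seed=seed)
    return node2vec_embed(network, dim=dim, seed=seed)
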