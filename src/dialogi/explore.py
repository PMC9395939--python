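"""Exploratory utilities over document feature vectors.

``project``: unit-normalize, PCA to 15 components, then 3D t-SNE with
euclidean distances.  Normalizing first makes euclidean and cosine distances
monotonically related, so the euclidean t-SNE respects the cosine geometry
the rest of the pipeline uses.

``query``: build a query vector exactly the way a document's feature vector
is built (per-category weighted average, unit-normalized, concatenated) and
rank documents by cosine similarity.  ``explain_hit`` breaks a hit down into
query-concept x in-text-concept similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .concept_spaces import DenseSpace
from .textproc import AnnotatedDocument


@dataclass
class Projection:
    doc_ids: list[str]
    coordinates: np.ndarray          # (n_nonzero, 3)
    labels: np.ndarray | None
    dropped_ids: list[str]
    pca_components: int = 15


@dataclass
class QueryResult:
    doc_ids: list[str]               # ranked, best first
    similarities: np.ndarray         # descending
    query_vector: np.ndarray
    query_concepts: dict[str, float]
    missing_concepts: list[str]


def project(feature_matrix: np.ndarray, doc_ids: list[str],
            labels: np.ndarray | None = None, seed: int = 0,
            pca_components: int = 15, perplexity: float = 30.0) -> Projection:
    """Zero rows dropped -> unit rows -> PCA(15) -> 3D t-SNE (euclidean)."""
    feature_matrix = np.asarray(feature_matrix, dtype=np.float64)
    norms = np.linalg.norm(feature_matrix, axis=1)
    keep = norms > 0
    n_keep = int(keep.sum())
    if n_keep < pca_components + 1:
        raise ValueError(
            f"only {n_keep} nonzero feature rows; need > {pca_components} "
            f"(lower pca_components for tiny inputs)")
    kept = feature_matrix[keep] / norms[keep, None]
    n_comp = min(pca_components, kept.shape[1], n_keep - 1)
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(kept)
    perp = min(perplexity, (n_keep - 1) / 3)
    coords = TSNE(n_components=3, metric="euclidean", random_state=seed,
                  perplexity=perp, init="pca", n_jobs=1).fit_transform(reduced)
    kept_ids = [d for d, k in zip(doc_ids, keep) if k]
    dropped = [d for d, k in zip(doc_ids, keep) if not k]
    kept_labels = np.asarray(labels)[keep] if labels is not None else None
    return Projection(doc_ids=kept_ids, coordinates=np.asarray(coords, dtype=np.float64),
                      labels=kept_labels, dropped_ids=dropped, pca_components=n_comp)


def _build_query_vector(concepts_with_weights: dict[str, float], disease_space: DenseSpace,
                        chemical_space: DenseSpace) -> tuple[np.ndarray, list[str]]:
    parts = {"disease": np.zeros(disease_space.dim),
             "chemical": np.zeros(chemical_space.dim)}
    weights = {"disease": {}, "chemical": {}}
    missing = []
    for cid, w in concepts_with_weights.items():
        if disease_space.get(cid) is not None:
            weights["disease"][cid] = w
        elif chemical_space.get(cid) is not None:
            weights["chemical"][cid] = w
        else:
            missing.append(cid)
    if not weights["disease"] and not weights["chemical"]:
        raise ValueError("no query concept is resolvable in either space")
    for category, space in (("disease", disease_space), ("chemical", chemical_space)):
        total = sum(weights[category].values())
        if total <= 0:
            continue
        v = np.zeros(space.dim)
        for cid, w in weights[category].items():
            v += (w / total) * space.get(cid)
        norm = np.linalg.norm(v)
        parts[category] = v / norm if norm > 0 else v
    return np.concatenate([parts["disease"], parts["chemical"]]), missing


def query(concepts_with_weights: dict[str, float], disease_space: DenseSpace,
          chemical_space: DenseSpace, feature_matrix: np.ndarray,
          doc_ids: list[str]) -> QueryResult:
    """Rank documents by cosine similarity against a constructed concept query."""
    qvec, missing = _build_query_vector(concepts_with_weights, disease_space, chemical_space)
    feature_matrix = np.asarray(feature_matrix, dtype=np.float64)
    norms = np.linalg.norm(feature_matrix, axis=1)
    qnorm = np.linalg.norm(qvec)
    sims = np.zeros(len(feature_matrix))
    nonzero = norms > 0
    sims[nonzero] = feature_matrix[nonzero] @ qvec / (norms[nonzero] * qnorm)
    order = np.argsort(-sims, kind="stable")
    return QueryResult(doc_ids=[doc_ids[i] for i in order], similarities=sims[order],
                       query_vector=qvec, query_concepts=dict(concepts_with_weights),
                       missing_concepts=missing)


def explain_hit(query_concepts: dict[str, float], doc: AnnotatedDocument,
                disease_space: DenseSpace, chemical_space: DenseSpace) -> list[dict]:
    """Cosine similarity between each query concept and each same-category
    in-text concept, sorted by decreasing in-text frequency (then similarity)."""
    spaces = {"disease": disease_space, "chemical": chemical_space}
    rows = []
    for category, space in spaces.items():
        q_ids = [c for c in query_concepts if space.get(c) is not None]
        for text_cid, freq in doc.rel_freq.get(category, {}).items():
            t_vec = space.get(text_cid)
            for q_cid in q_ids:
                q_vec = space.get(q_cid)
                if t_vec is None or q_vec is None:
                    sim = 0.0
                else:
                    denom = np.linalg.norm(q_vec) * np.linalg.norm(t_vec)
                    sim = float(q_vec @ t_vec / denom) if denom > 0 else 0.0
                rows.append({"category": category, "query_concept": q_cid,
                             "text_concept": text_cid, "text_freq": freq,
                             "similarity": sim})
    rows.sort(key=lambda r: (-r["text_freq"], -r["similarity"]))
    return rows
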