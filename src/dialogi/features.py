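"""Composite concept spaces and per-document external feature vectors.

A composite space concatenates member spaces column-wise in groups, reduces
each group by truncated SVD to a dimension or variance target, and
concatenates the reduced groups.  Members are aligned on the union of their
term universes with missing terms as zero rows, and are deliberately not
centred or scaled beforehand.

A document's feature vector is the concatenation (disease part first) of the
per-category relative-frequency-weighted averages of its concepts' vectors,
each part normalized to unit length (or kept zero).  Missing terms contribute
zero vectors but their frequency mass is not redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concept_spaces import DenseSpace, reduce_svd
from .textproc import AnnotatedDocument

# variance/dimension targets used for the published configuration
PAPER_PROFILE = {
    "disease": {"association_target": 103, "hierarchy_target": 47},   # -> 150 dims
    "chemical": {"association_target": 265, "hierarchy_target": 35},  # -> 300 dims
}


@dataclass
class CompositeGroup:
    """Member spaces concatenated then reduced together to one target."""
    spaces: list[DenseSpace]
    target: int | float   # int -> component count, float in (0,1) -> variance fraction


@dataclass
class TextFeatureVector:
    doc_id: str
    disease_part: np.ndarray
    chemical_part: np.ndarray
    has_disease: bool
    has_chemical: bool

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.disease_part, self.chemical_part])


def _aligned_matrix(space: DenseSpace, universe: list[str]) -> np.ndarray:
    out = np.zeros((len(universe), space.dim))
    for i, term in enumerate(universe):
        vec = space.get(term)
        if vec is not None:
            out[i] = vec
    return out


def compose_space(groups: list[CompositeGroup]) -> DenseSpace:
    """Concatenate -> group-wise truncated SVD -> concatenate."""
    all_spaces = [s for g in groups for s in g.spaces]
    if not all_spaces:
        raise ValueError("no member spaces")
    term_sets = [set(s.terms) for s in all_spaces]
    universe = sorted(set().union(*term_sets))
    if len(term_sets) > 1 and not set.intersection(*term_sets):
        raise ValueError("member spaces share no terms: refusing to compose "
                         "disjoint universes")
    parts = []
    for group in groups:
        stacked = np.hstack([_aligned_matrix(s, universe) for s in group.spaces])
        interim = DenseSpace(terms=universe, matrix=stacked, provenance="composite")
        if isinstance(group.target, (int, np.integer)) and not isinstance(group.target, bool):
            reduced = reduce_svd(interim, n_components=int(group.target))
        else:
            reduced = reduce_svd(interim, target_variance=float(group.target))
        parts.append(reduced.matrix)
    return DenseSpace(terms=universe, matrix=np.hstack(parts), provenance="composite")


def _category_part(doc: AnnotatedDocument, category: str, space: DenseSpace) -> np.ndarray:
    freqs = doc.rel_freq.get(category, {})
    v = np.zeros(space.dim)
    for cid, weight in freqs.items():
        vec = space.get(cid)
        if vec is not None:
            if len(vec) != space.dim:
                raise ValueError(f"{cid}: vector dim {len(vec)} != space dim {space.dim}")
            v = v + weight * vec
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def text_vector(doc: AnnotatedDocument, disease_space: DenseSpace,
                chemical_space: DenseSpace) -> TextFeatureVector:
    """Frequency-weighted average per category, unit-normalized, disease first.

    The ``has_*`` flags record annotation presence, not vector presence: a
    document whose every mentioned term is missing from the space keeps a zero
    part but a true flag.
    """
    return TextFeatureVector(
        doc_id=doc.doc_id,
        disease_part=_category_part(doc, "disease", disease_space),
        chemical_part=_category_part(doc, "chemical", chemical_space),
        has_disease=bool(doc.rel_freq.get("disease")),
        has_chemical=bool(doc.rel_freq.get("chemical")),
    )


def batch_featurize(docs: list[AnnotatedDocument], disease_space: DenseSpace,
                    chemical_space: DenseSpace,
                    ) -> tuple[np.ndarray, list[str], dict]:
    """Feature matrix (one row per document) plus a coverage report.

    The report gives, per class and overall, the fraction of documents with at
    least one disease and at least one chemical annotation.
    """
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate document ids")
    vectors = [text_vector(d, disease_space, chemical_space) for d in docs]
    matrix = np.stack([v.vector for v in vectors])

    report: dict = {"n_docs": len(docs), "overall": {}, "by_class": {}}
    flags = {"disease": np.array([v.has_disease for v in vectors]),
             "chemical": np.array([v.has_chemical for v in vectors])}
    for cat in ("disease", "chemical"):
        report["overall"][cat] = float(flags[cat].mean()) if docs else 0.0
    labels = np.array([-1 if d.label is None else d.label for d in docs])
    for cls in sorted(set(labels[labels >= 0])):
        mask = labels == cls
        report["by_class"][int(cls)] = {cat: float(flags[cat][mask].mean())
                                        for cat in ("disease", "chemical")}
    return matrix, ids, report
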