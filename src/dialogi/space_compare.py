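"""Agreement between two concept spaces: averaged Rank-Biased Overlap of
nearest-neighbour lists and CCA-based Pearson correlation.

RBO uses the extrapolated point estimate for (possibly non-conjoint,
possibly unequal-length) finite lists; neighbour lists are restricted to the
common-term universe *before* ranking and exclude the query term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .concept_spaces import DenseSpace, _unit_rows

logger = logging.getLogger(__name__)


@dataclass
class SpaceComparison:
    rbo_score: float
    cca_pearson: float
    n_common_terms: int
    p: float = 0.7

    def to_dict(self) -> dict:
        return {"rbo_score": self.rbo_score, "cca_pearson": self.cca_pearson,
                "n_common_terms": self.n_common_terms, "p": self.p}


def rbo(a: Sequence, b: Sequence, p: float = 0.7) -> float:
    """Extrapolated Rank-Biased Overlap of two ranked lists.

    Handles unequal lengths: let s and l be the short/long lengths and X_d the
    prefix-overlap at depth d (the short list contributes only its s items).
    The extrapolated score assumes the agreement seen at the evaluated depths
    persists, giving

        (1-p)/p * [ sum_{d=1}^{l} X_d/d p^d
                    + sum_{d=s+1}^{l} X_s (d-s)/(s d) p^d ]
        + [ (X_l - X_s)/l + X_s/s ] * p^l
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("ranked lists must not contain duplicates")
    if not a or not b:
        raise ValueError("ranked lists must be non-empty")
    short, long_ = (list(a), list(b)) if len(a) <= len(b) else (list(b), list(a))
    s, l = len(short), len(long_)
    short_set, long_set = set(), set()
    x = np.zeros(l + 1)
    for d in range(1, l + 1):
        if d <= s:
            short_set.add(short[d - 1])
        long_set.add(long_[d - 1])
        x[d] = len(short_set & long_set)
    xs, xl = x[s], x[l]
    total = 0.0
    for d in range(1, l + 1):
        term = x[d] / d
        if d > s:
            term += xs * (d - s) / (s * d)
        total += term * p**d
    return float((1 - p) / p * total + ((xl - xs) / l + xs / s) * p**l)


def neighbor_lists(space: DenseSpace, terms: list[str], n_neighbors: int = 100,
                   ) -> dict[str, list[str]]:
    """Cosine-ranked neighbour lists restricted to ``terms`` (self excluded;
    ties broken by ascending term id)."""
    rows = np.array([space.get(t) for t in terms])
    unit, _ = _unit_rows(rows.astype(np.float64))
    cos = unit @ unit.T
    out = {}
    for i, t in enumerate(terms):
        ranked = sorted((j for j in range(len(terms)) if j != i),
                        key=lambda j: (-cos[i, j], terms[j]))
        out[t] = [terms[j] for j in ranked[:n_neighbors]]
    return out


def _common_terms(space_a: DenseSpace, space_b: DenseSpace) -> list[str]:
    return sorted(set(space_a.terms) & set(space_b.terms))


def rbo_between_spaces(space_a: DenseSpace, space_b: DenseSpace,
                       n_neighbors: int = 100, p: float = 0.7) -> float:
    """Average per-term RBO of neighbour lists over the common-term universe."""
    common = _common_terms(space_a, space_b)
    if len(common) < 2:
        raise ValueError(f"need >= 2 common terms, got {len(common)}")
    lists_a = neighbor_lists(space_a, common, n_neighbors)
    lists_b = neighbor_lists(space_b, common, n_neighbors)
    scores = [rbo(lists_a[t], lists_b[t], p=p) for t in common]
    return float(np.mean(scores))


def _inv_sqrt(mat: np.ndarray, reg: float) -> np.ndarray:
    mat = mat + reg * np.eye(len(mat))
    vals, vecs = scipy.linalg.eigh(mat)
    cutoff = max(vals.max(), 0.0) * 1e-12
    inv = np.where(vals > cutoff, 1.0 / np.sqrt(np.maximum(vals, cutoff)), 0.0)
    return (vecs * inv) @ vecs.T


def cca_pearson(space_a: DenseSpace, space_b: DenseSpace, n_components: int = 3,
                reg: float = 1e-3) -> float:
    """Mean in-sample Pearson correlation of the first ``n_components``
    canonical-variable pairs fit on the common-term rows.

    When there are fewer samples than dimensions the problem is overfit;
    a ridge penalty (``reg``) keeps it well-posed (warned about).
    """
    common = _common_terms(space_a, space_b)
    if len(common) < 2:
        raise ValueError(f"need >= 2 common terms, got {len(common)}")
    x = np.array([space_a.get(t) for t in common], dtype=np.float64)
    y = np.array([space_b.get(t) for t in common], dtype=np.float64)
    n = len(common)
    if n <= max(x.shape[1], y.shape[1]):
        logger.warning("CCA with %d samples <= %d dims: overfit regime, ridge %.0e applied",
                       n, max(x.shape[1], y.shape[1]), reg)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    cxx = x.T @ x / n
    cyy = y.T @ y / n
    cxy = x.T @ y / n
    kx = _inv_sqrt(cxx, reg)
    ky = _inv_sqrt(cyy, reg)
    u, _s, vt = scipy.linalg.svd(kx @ cxy @ ky)
    k = min(n_components, u.shape[1], vt.shape[0])
    if k < n_components:
        logger.warning("only %d canonical pairs available (requested %d)", k, n_components)
    wx = kx @ u[:, :k]
    wy = ky @ vt[:k].T
    zx = x @ wx
    zy = y @ wy
    corrs = []
    for j in range(k):
        sx, sy = zx[:, j].std(), zy[:, j].std()
        if sx == 0 or sy == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(zx[:, j], zy[:, j])[0, 1]))
    return float(np.mean(corrs))


def compare_spaces(space_a: DenseSpace, space_b: DenseSpace, n_neighbors: int = 100,
                   p: float = 0.7, n_components: int = 3) -> SpaceComparison:
    common = _common_terms(space_a, space_b)
    return SpaceComparison(
        rbo_score=rbo_between_spaces(space_a, space_b, n_neighbors=n_neighbors, p=p),
        cca_pearson=cca_pearson(space_a, space_b, n_components=n_components),
        n_common_terms=len(common), p=p)
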