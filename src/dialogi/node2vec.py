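"""Weighted random-walk skip-gram embeddings (node2vec).

The canonical defaults are used: return parameter p = 1, in-out parameter
q = 1, 10 walks per node of length 80, window 10, 5 negative samples, one
epoch.  With p = q = 1 the walk is a plain first-order weighted random walk;
other settings take a (slower) second-order path.  Skip-gram with negative
sampling is trained in minibatches with a linearly decaying learning rate;
everything is seeded and single-threaded, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Node2VecParams:
    dim: int = 128
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    negative: int = 5
    epochs: int = 1
    alpha: float = 0.025       # initial learning rate, decays linearly to alpha/100
    batch_size: int = 1024


def _adjacency(nodes: list, edges: dict[tuple, float]):
    index = {n: i for i, n in enumerate(nodes)}
    neigh: list[list[int]] = [[] for _ in nodes]
    weights: list[list[float]] = [[] for _ in nodes]
    for (u, v), w in edges.items():
        iu, iv = index[u], index[v]
        neigh[iu].append(iv)
        weights[iu].append(w)
        neigh[iv].append(iu)
        weights[iv].append(w)
    neigh_arr = [np.asarray(n, dtype=np.int64) for n in neigh]
    prob_arr = []
    for w in weights:
        w = np.asarray(w, dtype=np.float64)
        prob_arr.append(w / w.sum() if w.size and w.sum() > 0 else w)
    return neigh_arr, prob_arr


def generate_walks(nodes: list, edges: dict[tuple, float], params: Node2VecParams,
                   rng: np.random.Generator) -> list[np.ndarray]:
    neigh, prob = _adjacency(nodes, edges)
    cum = [np.cumsum(p) for p in prob]
    n = len(nodes)
    second_order = not (params.p == 1.0 and params.q == 1.0)
    walks: list[np.ndarray] = []
    starts = np.tile(np.arange(n), params.walks_per_node)
    draws = rng.random((len(starts), params.walk_length - 1))
    for w_i, start in enumerate(starts):
        walk = [start]
        prev = -1
        for t in range(params.walk_length - 1):
            cur = walk[-1]
            nbrs = neigh[cur]
            if nbrs.size == 0:
                break
            if second_order and prev >= 0:
                adj = prob[cur].copy()
                prev_nbrs = set(neigh[prev].tolist())
                for k, cand in enumerate(nbrs):
                    if cand == prev:
                        adj[k] /= params.p
                    elif cand not in prev_nbrs:
                        adj[k] /= params.q
                nxt = int(nbrs[np.searchsorted(np.cumsum(adj / adj.sum()), draws[w_i, t])])
            else:
                nxt = int(nbrs[min(np.searchsorted(cum[cur], draws[w_i, t]),
                                   nbrs.size - 1)])
            prev = cur
            walk.append(nxt)
        walks.append(np.asarray(walk, dtype=np.int64))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) pairs with word2vec-style random window shrinking."""
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        spans = rng.integers(1, window + 1, size=L)
        for t in range(L):
            b = int(spans[t])
            lo, hi = max(0, t - b), min(L, t + b + 1)
            for s in range(lo, hi):
                if s != t:
                    centers.append(walk[t])
                    contexts.append(walk[s])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def _scatter_add(target: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """target[idx] += updates with duplicate indices, via sort + reduceat
    (much faster than np.add.at for wide update rows)."""
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    upd_s = updates[order]
    starts = np.concatenate([[0], np.nonzero(np.diff(idx_s))[0] + 1])
    target[idx_s[starts]] += np.add.reduceat(upd_s, starts, axis=0)


def _train_sgns(n_nodes: int, centers: np.ndarray, contexts: np.ndarray,
                params: Node2VecParams, rng: np.random.Generator) -> np.ndarray:
    dim = params.dim
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))
    # unigram^(3/4) noise distribution over context counts
    counts = np.bincount(contexts, minlength=n_nodes).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()

    n_pairs = len(centers)
    order = rng.permutation(n_pairs)
    total_steps = params.epochs * n_pairs
    seen = 0
    min_alpha = params.alpha / 100.0
    noise_cum = np.cumsum(noise)
    kp1 = params.negative + 1
    for _ in range(params.epochs):
        for lo in range(0, n_pairs, params.batch_size):
            idx = order[lo: lo + params.batch_size]
            c, o = centers[idx], contexts[idx]
            B = len(c)
            alpha = params.alpha + (min_alpha - params.alpha) * (seen / total_steps)
            seen += B
            neg = np.searchsorted(noise_cum, rng.random((B, params.negative)))
            np.clip(neg, 0, n_nodes - 1, out=neg)

            vc = w_in[c]                        # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)      # (B, 1+K)
            vt = w_out[targets]                 # (B, 1+K, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            g = (label - sig) * alpha            # (B, 1+K)
            grad_c = np.einsum("bk,bkd->bd", g, vt)
            # accumulate scattered updates as dense (n_nodes x B) matmuls:
            # far faster than ufunc.at for the small graphs used here
            cols = np.repeat(np.arange(B), kp1)
            g_out = np.bincount(targets.ravel() * B + cols, weights=g.ravel(),
                                minlength=n_nodes * B).reshape(n_nodes, B)
            w_out += g_out @ vc
            h_in = np.bincount(c * B + np.arange(B), weights=np.ones(B),
                               minlength=n_nodes * B).reshape(n_nodes, B)
            w_in += h_in @ grad_c
    return w_in


def node2vec(nodes: list, edges: dict[tuple, float], params: Node2VecParams | None = None,
             seed: int = 0) -> tuple[list, np.ndarray]:
    """Embed a weighted undirected graph; returns (nodes, matrix) with one
    ``params.dim``-length vector per node (isolated nodes keep their random
    initialization)."""
    params = params or Node2VecParams()
    nodes = sorted(nodes, key=str)
    rng = np.random.default_rng(seed)
    walks = generate_walks(nodes, edges, params, rng)
    centers, contexts = _skipgram_pairs(walks, params.window, rng)
    if len(centers) == 0:
        # graph with no edges: random vectors only
        return nodes, (rng.random((len(nodes), params.dim)) - 0.5) / params.dim
    matrix = _train_sgns(len(nodes), centers, contexts, params, rng)
    return nodes, matrix
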