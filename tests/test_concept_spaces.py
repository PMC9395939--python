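import math

import numpy as np
import pandas as pd
import pytest

from dialogi import concept_spaces as cs
from dialogi import synthetic_data as synth


def make_corpus(docs: dict[str, list[str]], kind: str = "association") -> cs.ConceptCorpus:
    return cs.ConceptCorpus(documents=docs, source_kind=kind)


class TestCorpusFromHierarchy:
    def test_prefix_words(self):
        table = pd.DataFrame([("D000001", "C06.552.195")], columns=["term_id", "tree_number"])
        corpus = cs.corpus_from_hierarchy(table)
        assert sorted(corpus.documents["D000001"]) == ["C06", "C06.552", "C06.552.195"]

    def test_multiple_trees_pool(self):
        table = pd.DataFrame([("D000001", "C06.552"), ("D000001", "C25.100")],
                             columns=["term_id", "tree_number"])
        corpus = cs.corpus_from_hierarchy(table)
        assert len(corpus.documents["D000001"]) == 4

    def test_shared_prefix_shared_word(self):
        table = pd.DataFrame([("D000001", "C06.552"), ("D000002", "C06.100")],
                             columns=["term_id", "tree_number"])
        corpus = cs.corpus_from_hierarchy(table)
        assert "C06" in corpus.documents["D000001"]
        assert "C06" in corpus.documents["D000002"]


class TestCorpusFromAssociations:
    def test_partner_document(self):
        table = pd.DataFrame([("A", "g1"), ("A", "g2")], columns=["term_id", "partner_id"])
        corpus = cs.corpus_from_associations(table)
        assert sorted(corpus.documents["A"]) == ["g1", "g2"]

    def test_no_partner_no_term(self):
        table = pd.DataFrame([("A", "g1")], columns=["term_id", "partner_id"])
        corpus = cs.corpus_from_associations(table)
        assert "B" not in corpus.documents

    def test_duplicate_row_multiplicity(self):
        table = pd.DataFrame([("A", "g1"), ("A", "g1")], columns=["term_id", "partner_id"])
        corpus = cs.corpus_from_associations(table)
        assert corpus.documents["A"] == ["g1", "g1"]


class TestTfidf:
    def test_max_df_boundary(self):
        docs = {f"t{i}": ["common"] for i in range(9)}
        docs["t9"] = ["rare"] * 9  # keeps t9 alive? no: "rare" has df 1 < 5 -> dropped
        for i in range(5):
            docs[f"t{i}"].append("kept")
        # "common" in 9 of 10 terms -> 90% > 80% -> dropped; "kept" df=5 kept
        space = cs.tfidf(make_corpus(docs))
        assert "common" not in space.vocab
        assert "kept" in space.vocab

    def test_min_df_boundary(self):
        docs = {f"t{i}": ["w4" if i < 4 else "w5"] for i in range(10)}
        for i in range(5):
            docs[f"t{i}"].append("anchor")
        # w4 df=4 -> dropped; w5 df=6 kept; anchor df=5 kept
        space = cs.tfidf(make_corpus(docs))
        assert "w4" not in space.vocab
        assert "w5" in space.vocab and "anchor" in space.vocab

    def test_toy_oracle_exact(self):
        # 6-term corpus, filters relaxed so everything survives
        docs = {"a": ["x", "x", "y"], "b": ["x", "z"], "c": ["y", "z", "z"],
                "d": ["x"], "e": ["y"], "f": ["z", "x"]}
        space = cs.tfidf(make_corpus(docs), min_df=1, max_df_frac=1.0)
        n = 6
        df = {"x": 4, "y": 3, "z": 3}
        dense = space.matrix.toarray()
        for ti, term in enumerate(space.terms):
            for wi, w in enumerate(space.vocab):
                tf = docs[term].count(w)
                expected = tf * (math.log(n / df[w]) + 1.0)
                assert abs(dense[ti, wi] - expected) < 1e-12

    def test_zero_rows_purged(self):
        docs = {f"t{i}": ["shared"] for i in range(6)}
        docs["lonely"] = ["once"]  # "once" df=1 -> dropped -> row all zero
        space = cs.tfidf(make_corpus(docs), min_df=5, max_df_frac=1.0)
        assert "lonely" not in space.terms
        assert len(space.terms) == 6

    def test_all_filtered_raises(self):
        docs = {"a": ["u"], "b": ["v"]}
        with pytest.raises(cs.EmptySpaceError):
            cs.tfidf(make_corpus(docs))

    def test_no_zero_vectors_invariant(self):
        tables, _ = synth.gen_association_tables(50, 300, seed=4)
        space = cs.tfidf(cs.corpus_from_associations(tables[0]))
        row_norms = np.abs(space.matrix).sum(axis=1)
        assert (np.asarray(row_norms).ravel() > 0).all()


class TestReduceSvd:
    def test_rank_one(self):
        matrix = np.outer(np.arange(1, 5, dtype=float), np.ones(3))
        space = cs.DenseSpace(terms=list("abcd"), matrix=matrix)
        red = cs.reduce_svd(space, target_variance=0.9)
        assert red.dim == 1
        assert red.explained_variance == pytest.approx(1.0)

    def test_k_matches_full_svd_oracle(self):
        rng = np.random.default_rng(0)
        matrix = rng.standard_normal((50, 20))
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(50)], matrix=matrix)
        red = cs.reduce_svd(space, target_variance=0.9)
        s = np.linalg.svd(matrix, compute_uv=False)
        evr = np.cumsum(s**2) / (s**2).sum()
        k_oracle = int(np.searchsorted(evr, 0.9 - 1e-12)) + 1
        assert red.dim == k_oracle

    def test_k_monotone_in_target(self):
        rng = np.random.default_rng(1)
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(30)],
                              matrix=rng.standard_normal((30, 15)))
        k90 = cs.reduce_svd(space, target_variance=0.9).dim
        k95 = cs.reduce_svd(space, target_variance=0.95).dim
        assert k95 >= k90

    def test_fixed_components(self):
        rng = np.random.default_rng(2)
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(20)],
                              matrix=rng.standard_normal((20, 10)))
        assert cs.reduce_svd(space, n_components=4).dim == 4

    def test_geometry_preserved(self):
        # full-rank reduction preserves pairwise inner products
        rng = np.random.default_rng(3)
        matrix = rng.standard_normal((12, 5))
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(12)], matrix=matrix)
        red = cs.reduce_svd(space, n_components=5)
        np.testing.assert_allclose(red.matrix @ red.matrix.T, matrix @ matrix.T, atol=1e-8)


class TestEmpiricalNull:
    def test_identical_vectors(self):
        space = cs.DenseSpace(terms=list("abcd"), matrix=np.ones((4, 3)))
        null = cs.empirical_null(space, n_pairs=100, seed=0)
        np.testing.assert_allclose(null, 1.0)

    def test_orthonormal_vectors(self):
        space = cs.DenseSpace(terms=list("abcd"), matrix=np.eye(4))
        null = cs.empirical_null(space, n_pairs=100, seed=0)
        np.testing.assert_allclose(null, 0.0, atol=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(10)],
                              matrix=rng.standard_normal((10, 4)))
        a = cs.empirical_null(space, n_pairs=500, seed=3)
        b = cs.empirical_null(space, n_pairs=500, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_sorted_and_sized(self):
        rng = np.random.default_rng(6)
        space = cs.DenseSpace(terms=[f"t{i}" for i in range(10)],
                              matrix=rng.standard_normal((10, 4)))
        null = cs.empirical_null(space, n_pairs=777, seed=1)
        assert len(null) == 777
        assert (np.diff(null) >= 0).all()


class TestPvalue:
    def test_above_all(self):
        null = np.sort(np.linspace(-1, 0.5, 100_000))
        assert cs.pvalue(0.99, null) == pytest.approx(1 / 100_001)

    def test_below_all(self):
        null = np.sort(np.linspace(0.0, 0.5, 1000))
        assert cs.pvalue(-0.5, null) == pytest.approx(1001 / 1001)

    def test_median(self):
        null = np.sort(np.linspace(-1, 1, 10_001))
        assert cs.pvalue(0.0, null) == pytest.approx(0.5, abs=0.001)

    def test_non_increasing_in_cos(self):
        rng = np.random.default_rng(7)
        null = np.sort(rng.uniform(-1, 1, 5000))
        xs = np.linspace(-1.1, 1.1, 200)
        ps = cs.pvalue(xs, null)
        assert (np.diff(ps) <= 0).all()


@pytest.fixture(scope="module")
def block_space():
    tables, blocks = synth.gen_association_tables(60, 300, n_blocks=4, seed=11)
    space = cs.reduce_svd(cs.tfidf(cs.corpus_from_associations(tables[0])), 0.9)
    null = cs.empirical_null(space, n_pairs=20_000, seed=3)
    return space, null, blocks


class TestBuildNetwork:
    def test_invariants(self, block_space):
        space, null, _ = block_space
        net = cs.build_network(space, null, n_neighbors=30, seed=3)
        for (u, v), w in net.edges.items():
            assert u != v
            assert u < v  # canonical undirected representation
        assert min(net.degree().values()) >= 3

    def test_weight_floor_or_forced(self, block_space):
        space, null, _ = block_space
        net = cs.build_network(space, null, n_neighbors=30, seed=3)
        unit = space.matrix / np.linalg.norm(space.matrix, axis=1, keepdims=True)
        cos = unit @ unit.T
        np.fill_diagonal(cos, -np.inf)
        forced = {}
        for i, t in enumerate(space.terms):
            ranked = sorted((j for j in range(len(space.terms)) if j != i),
                            key=lambda j: (-cos[i, j], space.terms[j]))
            forced[t] = {space.terms[j] for j in ranked[:3]}
        for (u, v), w in net.edges.items():
            assert w > 2.0 or v in forced[u] or u in forced[v]

    def test_term_order_invariance(self, block_space):
        space, null, _ = block_space
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(space.terms))
        shuffled = cs.DenseSpace(terms=[space.terms[i] for i in perm],
                                 matrix=space.matrix[perm])
        net_a = cs.build_network(space, null, n_neighbors=30)
        net_b = cs.build_network(shuffled, null, n_neighbors=30)
        assert set(net_a.edges) == set(net_b.edges)
        for key in net_a.edges:
            assert net_a.edges[key] == pytest.approx(net_b.edges[key])

    def test_too_few_terms(self):
        space = cs.DenseSpace(terms=list("abc"), matrix=np.eye(3))
        with pytest.raises(ValueError):
            cs.build_network(space, np.array([0.0, 0.5]), forced_k=3)

    def test_networkx_export(self, block_space):
        space, null, _ = block_space
        net = cs.build_network(space, null, n_neighbors=30)
        g = net.to_networkx()
        assert g.number_of_nodes() == len(space.terms)
        assert g.number_of_edges() == len(net.edges)


class TestNode2VecEmbed:
    def test_shape_and_determinism(self, block_space):
        space, null, _ = block_space
        net = cs.build_network(space, null, n_neighbors=30, seed=3)
        emb1 = cs.node2vec_embed(net, dim=128, seed=5)
        assert emb1.matrix.shape == (len(space.terms), 128)
        emb2 = cs.node2vec_embed(net, dim=128, seed=5)
        np.testing.assert_array_equal(emb1.matrix, emb2.matrix)

    def test_empty_network_raises(self):
        net = cs.SimilarityNetwork(nodes=[], edges={}, null_sample=np.array([]))
        with pytest.raises(ValueError):
            cs.node2vec_embed(net)
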