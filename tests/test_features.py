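import numpy as np
import pytest

from dialogi import features as ft
from dialogi import textproc as tp
from dialogi.concept_spaces import DenseSpace


def make_space(ids, matrix):
    return DenseSpace(terms=list(ids), matrix=np.asarray(matrix, dtype=float))


def make_doc(doc_id, disease_freqs=None, chemical_freqs=None, label=None):
    mentions = []
    for cat, freqs in (("disease", disease_freqs or {}), ("chemical", chemical_freqs or {})):
        for cid, n in freqs.items():
            mentions += [tp.ConceptMention(cid, cat, 0, 5)] * n
    return tp.AnnotatedDocument(doc_id, "", [], mentions,
                                tp.relative_frequencies(mentions), label=label)


@pytest.fixture
def dspace():
    return make_space(["A", "B", "C"], [[2, 0, 0], [0, 4, 0], [1, 1, 1]])


@pytest.fixture
def cspace():
    return make_space(["X", "Y"], [[3, 0], [0, 5]])


class TestTextVector:
    def test_single_disease(self, dspace, cspace):
        vec = ft.text_vector(make_doc("d", {"A": 3}), dspace, cspace)
        np.testing.assert_allclose(vec.disease_part, [1, 0, 0])
        np.testing.assert_allclose(vec.chemical_part, [0, 0])
        assert vec.has_disease and not vec.has_chemical

    def test_weighted_average_oracle(self, dspace, cspace):
        # diseases {A:3, B:1} -> weights 0.75/0.25 -> 0.75*[2,0,0]+0.25*[0,4,0]
        vec = ft.text_vector(make_doc("d", {"A": 3, "B": 1}), dspace, cspace)
        raw = 0.75 * np.array([2, 0, 0]) + 0.25 * np.array([0, 4, 0])
        np.testing.assert_allclose(vec.disease_part, raw / np.linalg.norm(raw), atol=1e-9)

    def test_no_annotations(self, dspace, cspace):
        vec = ft.text_vector(make_doc("d"), dspace, cspace)
        np.testing.assert_array_equal(vec.vector, np.zeros(5))
        assert not vec.has_disease and not vec.has_chemical

    def test_unit_or_zero_norm(self, dspace, cspace):
        for doc in (make_doc("a", {"A": 1, "C": 2}, {"X": 1}), make_doc("b"),
                    make_doc("c", None, {"Y": 4})):
            vec = ft.text_vector(doc, dspace, cspace)
            for part in (vec.disease_part, vec.chemical_part):
                norm = np.linalg.norm(part)
                assert norm == pytest.approx(0.0) or norm == pytest.approx(1.0, abs=1e-9)

    def test_missing_term_contributes_zero_keeps_mass(self, dspace, cspace):
        # "Z" missing: weighted average is 0.5*embed(A) with no renormalized weights
        vec = ft.text_vector(make_doc("d", {"A": 1, "Z": 1}), dspace, cspace)
        raw = 0.5 * np.array([2, 0, 0])
        np.testing.assert_allclose(vec.disease_part, raw / np.linalg.norm(raw))

    def test_all_terms_missing_flag_still_true(self, dspace, cspace):
        vec = ft.text_vector(make_doc("d", {"Z": 2}), dspace, cspace)
        np.testing.assert_array_equal(vec.disease_part, 0.0)
        assert vec.has_disease  # flags encode annotation presence, not vector presence

    def test_mention_order_invariance(self, dspace, cspace):
        m1 = [tp.ConceptMention("A", "disease", 0, 5), tp.ConceptMention("B", "disease", 0, 5)]
        m2 = list(reversed(m1))
        d1 = tp.AnnotatedDocument("d", "", [], m1, tp.relative_frequencies(m1))
        d2 = tp.AnnotatedDocument("d", "", [], m2, tp.relative_frequencies(m2))
        np.testing.assert_allclose(ft.text_vector(d1, dspace, cspace).vector,
                                   ft.text_vector(d2, dspace, cspace).vector)

    def test_count_scaling_invariance(self, dspace, cspace):
        v1 = ft.text_vector(make_doc("d", {"A": 1, "B": 3}), dspace, cspace)
        v2 = ft.text_vector(make_doc("d", {"A": 4, "B": 12}), dspace, cspace)
        np.testing.assert_allclose(v1.vector, v2.vector, atol=1e-12)


class TestBatchFeaturize:
    def test_matrix_and_coverage(self, dspace, cspace):
        docs = [make_doc("1", {"A": 1}, {"X": 1}, label=1),
                make_doc("2", None, None, label=0),
                make_doc("3", {"B": 2}, None, label=1),
                make_doc("4", {"C": 1}, {"Y": 1}, label=0)]
        matrix, ids, report = ft.batch_featurize(docs, dspace, cspace)
        assert matrix.shape == (4, 5)
        assert ids == ["1", "2", "3", "4"]
        assert report["overall"]["disease"] == 0.75
        assert report["by_class"][1]["disease"] == 1.0
        assert report["by_class"][0]["chemical"] == 0.5

    def test_row_norm_bound(self, dspace, cspace):
        docs = [make_doc(str(i), {"A": 1}, {"X": 1}) for i in range(5)]
        matrix, _, _ = ft.batch_featurize(docs, dspace, cspace)
        assert (np.linalg.norm(matrix, axis=1) <= np.sqrt(2) + 1e-9).all()

    def test_duplicate_ids_rejected(self, dspace, cspace):
        docs = [make_doc("1"), make_doc("1")]
        with pytest.raises(ValueError):
            ft.batch_featurize(docs, dspace, cspace)

    def test_synthetic_coverage_near_generator_fraction(self, small_processed, small_config):
        rng = np.random.default_rng(0)
        dsp = make_space([f"D{1 + i:06d}" for i in range(small_config.n_disease_terms)],
                         rng.standard_normal((small_config.n_disease_terms, 4)))
        csp = make_space([f"D{500001 + i:06d}" for i in range(small_config.n_chem_terms)],
                         rng.standard_normal((small_config.n_chem_terms, 4)))
        _, _, report = ft.batch_featurize(small_processed, dsp, csp)
        assert report["overall"]["disease"] == pytest.approx(
            1 - small_config.fraction_unannotated, abs=0.05)


class TestComposeSpace:
    def test_group_dims_add_up(self):
        rng = np.random.default_rng(1)
        terms = [f"T{i}" for i in range(60)]
        s1 = make_space(terms, rng.standard_normal((60, 20)))
        s2 = make_space(terms, rng.standard_normal((60, 15)))
        s3 = make_space(terms, rng.standard_normal((60, 10)))
        composite = ft.compose_space([ft.CompositeGroup([s1, s2], 12),
                                      ft.CompositeGroup([s3], 5)])
        assert composite.matrix.shape == (60, 17)
        assert composite.provenance == "composite"

    def test_variance_target(self):
        rng = np.random.default_rng(2)
        terms = [f"T{i}" for i in range(40)]
        s1 = make_space(terms, rng.standard_normal((40, 10)))
        composite = ft.compose_space([ft.CompositeGroup([s1], 0.9)])
        assert composite.matrix.shape[1] <= 10

    def test_union_of_terms_with_zero_fill(self):
        s1 = make_space(["A", "B"], [[1, 0], [0, 1]])
        s2 = make_space(["B", "C"], [[1, 1], [2, 2]])
        composite = ft.compose_space([ft.CompositeGroup([s1, s2], 3)])
        assert composite.terms == ["A", "B", "C"]

    def test_disjoint_universes_rejected(self):
        s1 = make_space(["A"], [[1.0, 0.0]])
        s2 = make_space(["B"], [[1.0, 0.0]])
        with pytest.raises(ValueError):
            ft.compose_space([ft.CompositeGroup([s1, s2], 1)])

    def test_single_member_span_preserved(self):
        # reduction to full rank spans the same column space (projector equality)
        rng = np.random.default_rng(3)
        terms = [f"T{i:02d}" for i in range(20)]  # zero-padded: composite sorts terms
        matrix = rng.standard_normal((20, 6))
        composite = ft.compose_space([ft.CompositeGroup([make_space(terms, matrix)], 6)])

        def projector(m):
            q, _ = np.linalg.qr(m)
            return q @ q.T

        np.testing.assert_allclose(projector(composite.matrix), projector(matrix), atol=1e-8)

    def test_paper_configuration_dims(self):
        # disease: reduce(concat(2 spaces)) -> 103 plus reduce(one) -> 47 => 150
        # chemical: reduce(concat(26 spaces)) -> 265 plus reduce(one) -> 35 => 300
        rng = np.random.default_rng(4)
        terms = [f"T{i}" for i in range(320)]
        d_members = [make_space(terms, rng.standard_normal((320, 64))) for _ in range(2)]
        d_mesh = make_space(terms, rng.standard_normal((320, 128)))
        disease = ft.compose_space([ft.CompositeGroup(d_members, 103),
                                    ft.CompositeGroup([d_mesh], 47)])
        assert disease.matrix.shape == (320, 150)
        c_members = [make_space(terms, rng.standard_normal((320, 16))) for _ in range(26)]
        c_mesh = make_space(terms, rng.standard_normal((320, 128)))
        chemical = ft.compose_space([ft.CompositeGroup(c_members, 265),
                                     ft.CompositeGroup([c_mesh], 35)])
        assert chemical.matrix.shape == (320, 300)
        # feature matrix built on those spaces is (n_docs, 450)
        docs = [make_doc(str(i), {"T1": 1}, {"T2": 1}) for i in range(3)]
        matrix, _, _ = ft.batch_featurize(docs, disease, chemical)
        assert matrix.shape == (3, 450)
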