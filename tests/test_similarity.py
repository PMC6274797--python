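import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pwcda
from pwcda.io import AnnotationCatalog, AssociationMatrix
from pwcda.similarity import DegenerateBandwidthError, SimilarityMatrix

terms = st.sets(st.sampled_from([f"t{i}" for i in range(12)]), max_size=10)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            (set(), set(), 0.0),  # no annotations carry no evidence
            (set(), {"a"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pwcda.jaccard(a, b) == expected

    @settings(derandomize=True, deadline=None)
    @given(terms, terms)
    def test_symmetric_bounded_and_self_similar(self, a, b):
        j = pwcda.jaccard(a, b)
        assert j == pwcda.jaccard(b, a)
        assert 0.0 <= j <= 1.0
        if a:
            assert pwcda.jaccard(a, a) == 1.0


class TestAnnotationSimilarityMatrix:
    def test_identical_nonempty_sets_score_one(self):
        cat = AnnotationCatalog(["a", "b"], {"a": frozenset("xy"), "b": frozenset("xy")})
        s = pwcda.annotation_similarity_matrix(cat, ["a", "b"])
        assert s.values[0, 1] == 1.0 and s.values[1, 0] == 1.0

    def test_empty_set_entity_scores_zero_everywhere(self):
        cat = AnnotationCatalog(["a", "b"], {"a": frozenset("xy")})
        s = pwcda.annotation_similarity_matrix(cat, ["a", "b"])
        assert s.values[1].tolist() == [0.0, 0.0]  # diagonal included
        assert s.values[0, 0] == 1.0  # annotated entity keeps diagonal 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_jaccard_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        ids = [f"e{k}" for k in range(n)]
        vocab = [f"t{k}" for k in range(20)]
        sets = {
            e: frozenset(rng.choice(vocab, size=rng.integers(0, 8), replace=False))
            for e in ids
        }
        s = pwcda.annotation_similarity_matrix(AnnotationCatalog(ids, sets), ids)
        for i in range(n):
            for j in range(n):
                assert s.values[i, j] == pytest.approx(
                    pwcda.jaccard(sets[ids[i]], sets[ids[j]]), abs=1e-12
                )
        assert np.allclose(s.values, s.values.T, atol=1e-12)


class TestGipBandwidth:
    def test_hand_evaluated_values(self):
        assert pwcda.gip_bandwidth(np.array([[1.0, 0.0], [0.0, 1.0]])) == 1.0
        assert pwcda.gip_bandwidth(np.array([[1.0, 1.0, 0.0]])) == 0.5

    def test_linear_in_gamma_prime(self):
        profiles = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert pwcda.gip_bandwidth(profiles, 2.0) == 2 * pwcda.gip_bandwidth(profiles, 1.0)

    def test_all_zero_profiles_degenerate(self):
        with pytest.raises(DegenerateBandwidthError):
            pwcda.gip_bandwidth(np.zeros((3, 4)))

    def test_zero_profiles_count_toward_the_mean(self):
        # mean over ALL entities: (2 + 0) / 2 = 1
        assert pwcda.gip_bandwidth(np.array([[1.0, 1.0], [0.0, 0.0]])) == 1.0


class TestGipKernel:
    def test_orthogonal_profiles_hand_value(self):
        m = AssociationMatrix(np.eye(2), ["d1", "d2"], ["c1", "c2"])
        k = pwcda.gip_kernel_matrix(m, "circrna")
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
        assert np.array_equal(np.diag(k.values), [1.0, 1.0])

    def test_identical_profiles_score_one(self):
        m = AssociationMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]), ["d1", "d2"], ["c1", "c2"])
        assert pwcda.gip_kernel_matrix(m, "circrna").values[0, 1] == 1.0

    def test_disease_axis_uses_rows(self):
        values = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        m = AssociationMatrix(values, ["d1", "d2"], ["c1", "c2", "c3"])
        assert pwcda.gip_kernel_matrix(m, "disease").values[0, 1] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_kernels_symmetric_psd_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = AssociationMatrix(
            (rng.random((4, 3)) < 0.5).astype(float),
            [f"d{i}" for i in range(4)],
            [f"c{j}" for j in range(3)],
        )
        for axis in ("circrna", "disease"):
            if m.values.sum() == 0:
                continue
            k = pwcda.gip_kernel_matrix(m, axis)
            assert np.array_equal(k.values, k.values.T)
            assert (k.values > 0).all() and (k.values <= 1).all()
            assert np.linalg.eigvalsh(k.values).min() >= -1e-9

    def test_all_zero_matrix_falls_back_to_identity_with_warning(self):
        m = AssociationMatrix(np.zeros((2, 3)), ["d1", "d2"], ["c1", "c2", "c3"])
        with pytest.warns(RuntimeWarning, match="identity"):
            k = pwcda.gip_kernel_matrix(m, "circrna")
        assert np.array_equal(k.values, np.eye(3))

    def test_unknown_axis_rejected(self):
        m = AssociationMatrix(np.eye(2), ["d1", "d2"], ["c1", "c2"])
        with pytest.raises(ValueError, match="axis"):
            pwcda.gip_kernel_matrix(m, "gene")


class TestIntegrateSimilarity:
    def _sim(self, values, kind="semantic"):
        return SimilarityMatrix(np.asarray(values, dtype=float), ["a", "b"], kind)

    def test_nonzero_primary_wins(self):
        out = pwcda.integrate_similarity(
            self._sim([[1, 0.2], [0.2, 1]]), self._sim([[1, 0.9], [0.9, 1]], "gip_circ")
        )
        assert out.values[0, 1] == 0.2

    def test_zero_primary_falls_back(self):
        out = pwcda.integrate_similarity(
            self._sim([[1, 0.0], [0.0, 1]]), self._sim([[1, 0.3], [0.3, 1]], "gip_circ")
        )
        assert out.values[0, 1] == 0.3

    def test_all_zero_primary_equals_fallback(self):
        fb = self._sim([[1, 0.4], [0.4, 1]], "gip_disease")
        out = pwcda.integrate_similarity(self._sim([[0, 0], [0, 0]]), fb)
        assert np.array_equal(out.values, fb.values)
        assert out.kind == "integrated_disease"

    def test_id_mismatch_rejected(self):
        a = SimilarityMatrix(np.eye(2), ["a", "b"], "semantic")
        b = SimilarityMatrix(np.eye(2), ["a", "c"], "gip_circ")
        with pytest.raises(ValueError, match="ids"):
            pwcda.integrate_similarity(a, b)

    def test_idempotent_when_fallback_shares_zeros(self):
        primary = self._sim([[1, 0.5], [0.5, 0]])
        fallback = self._sim([[1, 0.5], [0.5, 0]], "gip_circ")
        once = pwcda.integrate_similarity(primary, fallback)
        twice = pwcda.integrate_similarity(once, fallback)
        assert np.array_equal(once.values, twice.values)

    def test_integrated_diagonal_is_one_even_for_unannotated_entities(self):
        primary = self._sim([[0.0, 0.0], [0.0, 1.0]])  # entity "a" unannotated
        gip = self._sim([[1.0, 0.2], [0.2, 1.0]], "gip_circ")
        out = pwcda.integrate_similarity(primary, gip)
        assert np.array_equal(np.diag(out.values), [1.0, 1.0])
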