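import math

import numpy as np
import pytest

from anmda.data_model import (
    AssociationMatrix,
    PairIndex,
    SimilarityMatrix,
    UNDETECTED,
)
from anmda.similarity import (
    build_pair_features,
    gip_similarity,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    mirna_functional_similarity,
)
from tests.conftest import random_association_matrix


def naive_gip(adjacency: np.ndarray, gamma_prime: float) -> np.ndarray:
    """Double-loop oracle for the interaction-profile kernel (row profiles)."""
    n = adjacency.shape[0]
    gamma = gamma_prime / np.mean([np.dot(adjacency[i], adjacency[i]) for i in range(n)])
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = adjacency[i] - adjacency[j]
            out[i, j] = math.exp(-gamma * float(np.dot(diff, diff)))
    return out


class TestGip:
    def test_identity_fixture(self, identity_assoc):
        gs = gip_similarity(identity_assoc, "disease")
        # mean squared profile norm is 1, so gamma = 1 and GS = exp(-2)
        assert gs.get("d1", "d2") == pytest.approx(math.exp(-2), abs=1e-12)
        assert np.allclose(np.diag(gs.values), 1.0)

    def test_identical_profiles_give_one(self):
        a = AssociationMatrix(["m1", "m2"], ["d1", "d2"],
                              np.array([[1, 0], [1, 0]]))
        gs = gip_similarity(a, "mirna")
        assert gs.get("m1", "m2") == pytest.approx(1.0)

    def test_doubling_bandwidth_squares_entries(self, identity_assoc):
        g1 = gip_similarity(identity_assoc, "mirna", gamma_prime=1.0)
        g2 = gip_similarity(identity_assoc, "mirna", gamma_prime=2.0)
        assert np.allclose(g2.values, g1.values ** 2)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = random_association_matrix(rng)
            for axis, profiles in (("mirna", a.adjacency),
                                   ("disease", a.adjacency.T)):
                got = gip_similarity(a, axis).values
                want = naive_gip(profiles.astype(float), 1.0)
                np.fill_diagonal(want, 1.0)
                assert np.abs(got - want).max() < 1e-12

    def test_all_zero_matrix_rejected(self):
        a = AssociationMatrix(["m1"], ["d1"], np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="zero"):
            gip_similarity(a, "mirna")


class TestFunctionalSimilarity:
    def test_shared_single_disease(self, toy_combined_ss):
        a = AssociationMatrix(["m1", "m2"], ["B"], np.array([[1], [1]]))
        fsm = mirna_functional_similarity(a, toy_combined_ss)
        assert fsm.get("m1", "m2") == pytest.approx(1.0)

    def test_best_match_average_on_toy_pair(self, toy_combined_ss):
        a = AssociationMatrix(["m1", "m2"], ["B", "C"], np.array([[1, 0], [0, 1]]))
        fsm = mirna_functional_similarity(a, toy_combined_ss)
        expected = (2.25 / 3.25 + 0.5) / 2  # SS(B, C)
        assert fsm.get("m1", "m2") == pytest.approx(expected)

    def test_self_similarity_one_where_defined(self, toy_combined_ss):
        a = AssociationMatrix(["m1"], ["B", "C"], np.array([[1, 1]]))
        fsm = mirna_functional_similarity(a, toy_combined_ss)
        assert fsm.get("m1", "m1") == pytest.approx(1.0)

    def test_unassociated_mirna_is_missing_not_zero(self, toy_combined_ss):
        a = AssociationMatrix(["m1", "m2"], ["B"], np.array([[1], [0]]))
        fsm = mirna_functional_similarity(a, toy_combined_ss)
        assert np.isnan(fsm.get("m1", "m2"))
        assert fsm.get("m1", "m1") == pytest.approx(1.0)

    def test_disease_without_semantic_row_ignored(self, toy_combined_ss):
        # m2's only disease is absent from the semantic matrix -> missing row
        a = AssociationMatrix(["m1", "m2"], ["B", "unknown"],
                              np.array([[1, 0], [0, 1]]))
        fsm = mirna_functional_similarity(a, toy_combined_ss)
        assert np.isnan(fsm.get("m1", "m2"))

    def test_symmetric_and_bounded(self, toy_combined_ss):
        rng = np.random.default_rng(5)
        diseases = list(toy_combined_ss.labels)
        for _ in range(10):
            adj = (rng.random((4, len(diseases))) < 0.5).astype(int)
            adj[0, 0] = 1  # ensure at least one association
            a = AssociationMatrix([f"m{i}" for i in range(4)], diseases, adj)
            fsm = mirna_functional_similarity(a, toy_combined_ss)
            finite = np.isfinite(fsm.values)
            assert (fsm.values[finite] >= -1e-12).all()
            assert (fsm.values[finite] <= 1 + 1e-12).all()
            assert np.array_equal(finite, finite.T)


class TestIntegration:
    def test_average_where_semantic_exists(self):
        ss = SimilarityMatrix(["d1", "d2"],
                              np.array([[1.0, 0.5962], [0.5962, 1.0]]))
        gs = SimilarityMatrix(["d1", "d2"],
                              np.array([[1.0, 0.13534], [0.13534, 1.0]]))
        out = integrate_disease_similarity(ss, gs)
        assert out.get("d1", "d2") == pytest.approx((0.5962 + 0.13534) / 2)

    def test_fallback_to_gip_for_uncovered_disease(self):
        ss = SimilarityMatrix(["d1"], np.array([[1.0]]))
        gs = SimilarityMatrix(["d1", "d2"],
                              np.array([[1.0, 0.4], [0.4, 1.0]]))
        out = integrate_disease_similarity(ss, gs)
        assert out.get("d1", "d2") == pytest.approx(0.4)
        assert out.get("d2", "d2") == pytest.approx(1.0)

    def test_idempotent_when_values_agree(self):
        ss = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = integrate_disease_similarity(ss, ss)
        assert out.get("d1", "d2") == pytest.approx(0.3)

    def test_mirna_integration_mirrors_disease(self):
        fsm = SimilarityMatrix(["m1", "m2"], np.array([[1.0, np.nan], [np.nan, 1.0]]),
                               allow_missing=True)
        gs = SimilarityMatrix(["m1", "m2"], np.array([[1.0, 0.7], [0.7, 1.0]]))
        out = integrate_mirna_similarity(fsm, gs)
        assert out.get("m1", "m2") == pytest.approx(0.7)

    def test_unit_diagonal_and_symmetry_preserved(self):
        rng = np.random.default_rng(9)
        n = 5
        half = rng.random((n, n)) * 0.5
        ss_vals = (half + half.T) / 2
        np.fill_diagonal(ss_vals, 1.0)
        labels = [f"d{i}" for i in range(n)]
        ss = SimilarityMatrix(labels, ss_vals)
        gs = SimilarityMatrix(labels, np.eye(n))
        out = integrate_disease_similarity(ss, gs)
        assert np.allclose(out.values, out.values.T)
        assert np.allclose(np.diag(out.values), 1.0)


class TestPairFeatures:
    def _matrices(self):
        sm = SimilarityMatrix(["m1", "m2"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        sd = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        return sm, sd

    def test_feature_length_and_content(self):
        sm, sd = self._matrices()
        ds = build_pair_features(sm, sd, PairIndex([(0, 0)], label=UNDETECTED))
        assert ds.n_features == 4
        assert ds.X[0].tolist() == [1.0, 0.2, 1.0, 0.8]

    def test_shared_mirna_shares_first_block(self):
        sm, sd = self._matrices()
        ds = build_pair_features(
            sm, sd, PairIndex([(1, 0), (1, 1)], label=UNDETECTED)
        )
        assert np.array_equal(ds.X[0, :2], ds.X[1, :2])
        assert not np.array_equal(ds.X[0, 2:], ds.X[1, 2:])

    def test_out_of_bounds_pair_rejected(self):
        sm, sd = self._matrices()
        with pytest.raises(IndexError):
            build_pair_features(sm, sd, PairIndex([(2, 0)], label=UNDETECTED))

    def test_catalogue_scale_dimensionality(self):
        # 495 miRNAs + 383 diseases concatenate to 878 features
        assert 495 + 383 == 878
        rng = np.random.default_rng(1)
        a = random_association_matrix(rng, n_m=6, n_d=4)
        sm = SimilarityMatrix(a.mirna_ids, np.eye(6))
        sd = SimilarityMatrix(a.disease_ids, np.eye(4))
        from anmda.data_model import undetected_pairs

        ds = build_pair_features(sm, sd, undetected_pairs(a))
        assert ds.n_features == 10
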