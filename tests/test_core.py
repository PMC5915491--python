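"""Seed optimization, restart walks, Pearson scoring, and the full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gstrw import (
    AssociationMatrix,
    GstrwParams,
    LabeledSquareMatrix,
    GstrwModel,
    column_normalize,
    global_similarity,
    optimize_disease_seed,
    optimize_mirna_seed,
    pearson_profile_scores,
    predict,
    random_walk_restart,
)


def _toy():
    """3 miRNAs x 3 diseases with mild structure."""
    a = AssociationMatrix(
        ["m1", "m2", "m3"], ["d1", "d2", "d3"], [[1, 0, 0], [0, 1, 0], [1, 0, 1]]
    )
    sd = LabeledSquareMatrix(
        ["d1", "d2", "d3"], [[1.0, 0.2, 0.7], [0.2, 1.0, 0.3], [0.7, 0.3, 1.0]]
    )
    sim = LabeledSquareMatrix(
        ["m1", "m2", "m3"], [[1.0, 0.5, 0.6], [0.5, 1.0, 0.1], [0.6, 0.1, 1.0]]
    )
    return a, sim, sd


class TestSeedOptimization:
    def test_zero_weight_collapses_to_association_indicator(self):
        a, sim, sd = _toy()
        g = global_similarity(sd, 0.8)
        seed = optimize_disease_seed(a, g, lam=0.0, disease_index=0)
        np.testing.assert_allclose(seed, [0.5, 0.0, 0.5])  # indicator of {m1, m3}, L1-normalized

    def test_orphan_disease_borrows_from_similar_diseases(self):
        a, sim, sd = _toy()
        a.values[:, 0] = 0.0  # make d1 an orphan
        g = global_similarity(sd, 0.8)
        seed = optimize_disease_seed(a, g, lam=0.2, disease_index=0)
        assert seed.sum() == pytest.approx(1.0)
        # d3 (similar to d1) is associated with m3, so m3 must receive mass
        assert seed[2] > 0

    def test_seed_matches_direct_formula(self):
        a, sim, sd = _toy()
        g = global_similarity(sd, 0.8)
        lam, i = 0.3, 1
        expected = a.values[:, i].copy()
        for j in range(3):
            if j != i:
                expected += lam * g.values[j, i] * a.values[:, j]
        expected /= expected.sum()
        np.testing.assert_allclose(
            optimize_disease_seed(a, g, lam, i), expected, atol=1e-12
        )

    def test_identical_diseases_get_identical_seeds(self):
        # two diseases with identical similarity rows and association columns
        a = AssociationMatrix(["m1", "m2"], ["d1", "d2", "d3"], [[1, 1, 0], [0, 0, 1]])
        sd = LabeledSquareMatrix(
            ["d1", "d2", "d3"], [[1.0, 0.9, 0.4], [0.9, 1.0, 0.4], [0.4, 0.4, 1.0]]
        )
        g = global_similarity(sd, 0.8)
        s1 = optimize_disease_seed(a, g, 0.2, 0)
        s2 = optimize_disease_seed(a, g, 0.2, 1)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_mirna_seed_mirrors_disease_seed(self):
        a, sim, sd = _toy()
        g = global_similarity(sim, 0.8)
        seed = optimize_mirna_seed(a, g, eta=0.0, mirna_index=2)
        np.testing.assert_allclose(seed, [0.5, 0.0, 0.5])  # diseases {d1, d3}

    def test_all_zero_matrix_yields_zero_seed(self):
        a = AssociationMatrix(["m1", "m2"], ["d1", "d2"], [[0, 0], [0, 0]])
        g = global_similarity(
            LabeledSquareMatrix(["d1", "d2"], [[1, 0.5], [0.5, 1]]), 0.8
        )
        seed = optimize_disease_seed(a, g, lam=0.5, disease_index=0)
        np.testing.assert_array_equal(seed, [0.0, 0.0])


class TestRandomWalkRestart:
    def test_two_node_closed_form(self):
        # stationary = 0.2 * (I - 0.8*S)^-1 @ [1,0] = [5/9, 4/9]
        s_bar = np.array([[0.0, 1.0], [1.0, 0.0]])
        x = random_walk_restart(s_bar, np.array([1.0, 0.0]), restart=0.2, tol=1e-12)
        np.testing.assert_allclose(x, [5 / 9, 4 / 9], atol=1e-10)

    def test_full_restart_returns_seed(self):
        s_bar = np.array([[0.0, 1.0], [1.0, 0.0]])
        seed = np.array([0.3, 0.7])
        np.testing.assert_allclose(random_walk_restart(s_bar, seed, restart=1.0), seed)

    @pytest.mark.parametrize("seed_int", range(10))
    def test_matches_linear_solve_on_random_instances(self, seed_int):
        r = np.random.default_rng(seed_int)
        n = int(r.integers(10, 60))
        raw = r.random((n, n))
        s_bar = raw / raw.sum(axis=0)
        seed = r.random(n)
        seed /= seed.sum()
        restart = float(r.uniform(0.1, 0.9))
        x = random_walk_restart(s_bar, seed, restart, tol=1e-10)
        direct = restart * np.linalg.solve(np.eye(n) - (1 - restart) * s_bar, seed)
        np.testing.assert_allclose(x, direct, atol=1e-6)

    def test_conserves_probability_on_stochastic_network(self, rng):
        raw = rng.random((15, 15))
        s_bar = raw / raw.sum(axis=0)
        seed = np.zeros(15)
        seed[3] = 1.0
        x = random_walk_restart(s_bar, seed, restart=0.2)
        assert abs(x.sum() - 1.0) < 1e-9
        assert np.all(x >= 0)

    def test_zero_seed_stays_zero(self):
        s_bar = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(
            random_walk_restart(s_bar, np.zeros(2), restart=0.2), np.zeros(2)
        )

    def test_unnormalized_seed_rejected(self):
        s_bar = np.eye(2)
        with pytest.raises(ValueError, match="sum to 1"):
            random_walk_restart(s_bar, np.array([0.5, 0.4]), restart=0.2)

    def test_iteration_cap_raises_with_residual(self):
        s_bar = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ArithmeticError, match="residual"):
            random_walk_restart(
                s_bar, np.array([1.0, 0.0]), restart=0.2, tol=1e-12, max_iter=2
            )

    def test_batched_columns_match_individual_walks(self, rng):
        raw = rng.random((8, 8))
        s_bar = raw / raw.sum(axis=0)
        seeds = rng.random((8, 4))
        seeds /= seeds.sum(axis=0)
        batch = random_walk_restart(s_bar, seeds, restart=0.3, tol=1e-12)
        for k in range(4):
            single = random_walk_restart(s_bar, seeds[:, k], restart=0.3, tol=1e-12)
            np.testing.assert_allclose(batch[:, k], single, atol=1e-9)


class TestPearsonScores:
    def test_self_correlation_is_one(self):
        g = LabeledSquareMatrix(["a", "b", "c"], [[1, 0.2, 0.1], [0.2, 1, 0.4], [0.1, 0.4, 1]])
        scores = pearson_profile_scores(g.values[:, 1], g)
        assert scores[1] == pytest.approx(1.0)

    def test_constant_vector_scores_zero_everywhere(self):
        g = LabeledSquareMatrix(["a", "b"], [[1, 0.2], [0.2, 1]])
        np.testing.assert_array_equal(
            pearson_profile_scores(np.array([0.5, 0.5]), g), [0.0, 0.0]
        )

    def test_constant_profile_column_scores_zero(self):
        g = LabeledSquareMatrix(["a", "b"], [[0.3, 0.1], [0.3, 0.9]])
        scores = pearson_profile_scores(np.array([0.7, 0.3]), g)
        assert scores[0] == 0.0

    def test_length_mismatch_rejected(self):
        g = LabeledSquareMatrix(["a", "b"], [[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="length"):
            pearson_profile_scores(np.zeros(3), g)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_matches_sum_formula_oracle(self, seed_int):
        """Agrees with the textbook sum-based Pearson formula."""
        r = np.random.default_rng(seed_int)
        x = r.random(6)
        g = LabeledSquareMatrix([f"e{i}" for i in range(6)], r.random((6, 6)))
        scores = pearson_profile_scores(x, g)
        n = 6
        for k in range(n):
            y = g.values[:, k]
            num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
            den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
                n * np.sum(y**2) - np.sum(y) ** 2
            )
            expected = num / den if den > 0 else 0.0
            assert scores[k] == pytest.approx(expected, abs=1e-12)


class TestPredict:
    def test_w_one_reduces_to_mirna_tier(self):
        a, sim, sd = _toy()
        f, f_m, f_d = predict(a, sim, sd, GstrwParams(w=1.0))
        np.testing.assert_array_equal(f.values, f_m.values.T)

    def test_w_zero_reduces_to_disease_tier(self):
        a, sim, sd = _toy()
        f, f_m, f_d = predict(a, sim, sd, GstrwParams(w=0.0))
        np.testing.assert_array_equal(f.values, f_d.values)

    def test_fusion_is_convex_combination(self):
        a, sim, sd = _toy()
        p = GstrwParams(w=0.6)
        f, f_m, f_d = predict(a, sim, sd, p)
        np.testing.assert_allclose(
            f.values, 0.6 * f_m.values.T + 0.4 * f_d.values, atol=1e-15
        )

    def test_deterministic_bit_identical_reruns(self):
        a, sim, sd = _toy()
        f1, _, _ = predict(a, sim, sd)
        f2, _, _ = predict(a, sim, sd)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_disease_label_permutation_equivariance(self, rng):
        a, sim, sd = _toy()
        f, _, _ = predict(a, sim, sd)
        perm = [2, 0, 1]
        sd_p = LabeledSquareMatrix(
            [sd.labels[k] for k in perm], sd.values[np.ix_(perm, perm)]
        )
        a_p = AssociationMatrix(
            a.mirna_labels, [a.disease_labels[k] for k in perm], a.values[:, perm]
        )
        f_p, _, _ = predict(a_p, sim, sd_p)
        np.testing.assert_allclose(f_p.values, f.values[:, perm], atol=1e-9)

    def test_label_mismatch_rejected(self):
        a, sim, sd = _toy()
        bad = AssociationMatrix(["x1", "x2", "x3"], a.disease_labels, a.values)
        with pytest.raises(ValueError, match="labels"):
            GstrwModel(sim, sd).predict(bad)

    def test_known_pairs_outscore_null_pairs_on_fixture(self, strong_fixture):
        fx = strong_fixture
        f, _, _ = predict(fx["a"], fx["sim"], fx["sd"])
        true = fx["a"].values == 1
        assert f.values[true].mean() > f.values[~true].mean()


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": 0.0},
            {"theta": 1.0},
            {"alpha": -0.1},
            {"beta": 1.2},
            {"lam": -1.0},
            {"w": 1.5},
            {"tol": 0.0},
            {"max_iter": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GstrwParams(**kwargs)

    def test_defaults_match_reference_setting(self):
        p = GstrwParams()
        assert (p.gamma, p.theta, p.alpha, p.beta) == (0.2, 0.2, 0.8, 0.8)
        assert (p.lam, p.eta, p.w, p.tol) == (0.2, 0.2, 0.6, 1e-6)
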