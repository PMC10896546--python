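import numpy as np
import pytest

from ecolandnet.qap import (
    adjacency_matrix,
    difference_matrix,
    mrqap_regression,
    qap_correlation,
)


def random_symmetric(rng, n):
    M = rng.normal(size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return M


def random_ties(rng, n, p=0.25):
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0)
    return A


class TestDesignMatrices:
    def test_difference_hand_values(self):
        D = difference_matrix([1.0, 4.0, 6.0])
        np.testing.assert_allclose(D, [[0, 3, 5], [3, 0, 2], [5, 2, 0]])

    def test_constant_values_zero_matrix(self):
        np.testing.assert_allclose(difference_matrix([2.0, 2.0, 2.0]), 0.0)

    def test_symmetric_for_random_inputs(self):
        rng = np.random.default_rng(0)
        D = difference_matrix(rng.normal(size=10))
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)

    def test_mapping_with_missing_city_rejected(self):
        with pytest.raises(KeyError, match="C03"):
            difference_matrix({"C01": 1.0, "C02": 2.0},
                              cities=["C01", "C02", "C03"])

    def test_adjacency_symmetric_closure(self):
        S = adjacency_matrix([("a", "b")], ["a", "b", "c"])
        assert S.sum() == 2
        assert S[0, 1] == S[1, 0] == 1

    def test_adjacency_idempotent_under_duplicates(self):
        cities = ["a", "b", "c"]
        once = adjacency_matrix([("a", "b")], cities)
        twice = adjacency_matrix([("a", "b"), ("b", "a"), ("a", "b")], cities)
        np.testing.assert_array_equal(once, twice)

    def test_adjacency_empty_and_unknown(self):
        assert adjacency_matrix([], ["a", "b"]).sum() == 0
        with pytest.raises(KeyError, match="z"):
            adjacency_matrix([("a", "z")], ["a", "b"])


class TestQapCorrelation:
    def test_identity_gives_r_one_minimal_p(self):
        rng = np.random.default_rng(1)
        R = random_ties(rng, 12)
        out = qap_correlation(R, R, n_perm=99, seed=0)
        assert out["r"] == pytest.approx(1.0)
        assert out["p_two_tailed"] == pytest.approx(1 / 100)

    def test_joint_relabeling_leaves_r(self):
        rng = np.random.default_rng(2)
        R = random_ties(rng, 10)
        X = random_symmetric(rng, 10)
        r0 = qap_correlation(R, X, n_perm=9, seed=0)["r"]
        p = rng.permutation(10)
        r1 = qap_correlation(R[np.ix_(p, p)], X[np.ix_(p, p)],
                             n_perm=9, seed=0)["r"]
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        R, X = random_ties(rng, 10), random_symmetric(rng, 10)
        a = qap_correlation(R, X, n_perm=199, seed=7)
        b = qap_correlation(R, X, n_perm=199, seed=7)
        assert a == b

    def test_zero_variance_rejected(self):
        R = np.zeros((5, 5))
        X = random_symmetric(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="variance"):
            qap_correlation(R, X, n_perm=9, seed=0)

    def test_null_rejection_rate_small_calibration(self):
        # quick calibration check (the full one runs in the acceptance suite)
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 120
        for s in range(n_sim):
            R = random_ties(rng, 15)
            X = random_symmetric(rng, 15)
            p = qap_correlation(R, X, n_perm=199, seed=s)["p_two_tailed"]
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_sim <= 0.10


class TestMrqap:
    def test_perfect_fit_single_predictor(self):
        rng = np.random.default_rng(5)
        R = random_ties(rng, 10)
        res = mrqap_regression(R, {"self": R}, n_perm=99, seed=0)
        assert res.table.loc[0, "beta"] == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(6)
        R = random_ties(rng, 8)
        X = random_symmetric(rng, 8)
        with pytest.raises(ValueError, match="collinear"):
            mrqap_regression(R, {"a": X, "b": 2 * X}, n_perm=9, seed=0)

    def test_noise_predictor_leaves_other_betas(self):
        # an added orthogonally-shuffled noise predictor must not move the
        # informative coefficients beyond numerical noise of the OLS solve
        rng = np.random.default_rng(7)
        n = 14
        X1 = random_symmetric(rng, n)
        R = (X1 > 0.3).astype(float)
        np.fill_diagonal(R, 0)
        base = mrqap_regression(R, {"x1": X1}, n_perm=9, seed=0)
        noise_a = random_symmetric(rng, n)
        p = rng.permutation(n)
        noise_b = noise_a[np.ix_(p, p)]
        with_a = mrqap_regression(R, {"x1": X1, "noise": noise_a},
                                  n_perm=9, seed=0)
        with_b = mrqap_regression(R, {"x1": X1, "noise": noise_b},
                                  n_perm=9, seed=0)
        # x1's estimate is stable across which noise realisation is used
        assert with_a.table.loc[0, "beta"] == pytest.approx(
            base.table.loc[0, "beta"], abs=0.05)
        assert with_b.table.loc[0, "beta"] == pytest.approx(
            base.table.loc[0, "beta"], abs=0.05)

    def test_bitwise_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        R = random_ties(rng, 12)
        preds = {"x": random_symmetric(rng, 12),
                 "y": random_symmetric(rng, 12)}
        a = mrqap_regression(R, preds, n_perm=299, seed=11)
        b = mrqap_regression(R, preds, n_perm=299, seed=11)
        assert a.table.equals(b.table)
        assert a.r_squared == b.r_squared

    def test_dsp_method_runs_and_agrees_on_betas(self):
        rng = np.random.default_rng(9)
        R = random_ties(rng, 12)
        preds = {"x": random_symmetric(rng, 12),
                 "y": random_symmetric(rng, 12)}
        y_perm = mrqap_regression(R, preds, n_perm=99, seed=0)
        dsp = mrqap_regression(R, preds, n_perm=99, seed=0, method="dsp")
        np.testing.assert_allclose(dsp.table["beta"], y_perm.table["beta"],
                                   atol=1e-12)
        assert ((dsp.table["p_reg"] > 0) & (dsp.table["p_reg"] <= 1)).all()

    def test_stars_follow_thresholds(self):
        rng = np.random.default_rng(10)
        R = random_ties(rng, 10)
        res = mrqap_regression(R, {"self": R}, n_perm=999, seed=0)
        assert res.table.loc[0, "stars"] == "***"
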