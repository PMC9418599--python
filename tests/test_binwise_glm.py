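import numpy as np
import pytest

from tapjid.binwise_glm import (
    RankDeficientError,
    build_response,
    cluster_correct,
    fdr_correct,
    fit_bin,
    make_design,
    mass_univariate,
    scalar_robust_regression,
)
from tapjid.jid_core import JIDConfig, compute_jid


def _design(rng, n, with_gender=True):
    cols = {"age": rng.uniform(16, 86, n)}
    if with_gender:
        cols["gender"] = rng.integers(1, 3, n).astype(float)
    return make_design(cols)


class TestBuildResponse:
    def test_zero_replacement_uses_global_min(self):
        M = np.array([[0.1, 0.9], [0.0, 1.0], [0.01, 0.99]])
        M = np.hstack([M, np.full((3, 2), 0.001)])  # global min 0.001
        Y = build_response(M, already_stacked=True)
        assert Y[1, 0] == pytest.approx(np.log10(0.001))
        assert Y[0, 0] == pytest.approx(-1.0)
        assert Y[2, 0] == pytest.approx(-2.0)

    def test_no_zeros_plain_log10(self, rng):
        M = rng.uniform(0.001, 1.0, size=(5, 4))
        Y = build_response(M, already_stacked=True)
        np.testing.assert_allclose(Y, np.log10(M))

    def test_all_zero_column_warns(self):
        M = np.array([[0.5, 0.0], [0.5, 0.0]])
        with pytest.warns(UserWarning):
            Y = build_response(M, already_stacked=True)
        assert np.all(Y[:, 1] == np.log10(0.5))

    def test_from_jid_grids(self, rng):
        cfg = JIDConfig()
        grids = [
            compute_jid(10.0 ** rng.uniform(1, 4, (30, 2)), cfg)
            for _ in range(3)
        ]
        Y = build_response(grids)
        assert Y.shape == (3, 2500)
        assert np.all(np.isfinite(Y))


class TestFitBin:
    def test_noise_free_recovery(self, rng):
        X, names = _design(rng, 60)
        y = 2.0 * X[:, 0] + 1.0
        fit = fit_bin(y, X, names)
        assert fit.coef("age") == pytest.approx(2.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_irls_matches_normal_equations_at_converged_weights(self, rng):
        # dual route: closed-form weighted normal equations at the weights
        # implied by the converged coefficients
        from tapjid.binwise_glm import BISQUARE_C, MAD_TO_SIGMA

        X, names = _design(rng, 200)
        y = 0.5 * X[:, 0] + rng.normal(0, 1, 200)
        fit = fit_bin(y, X, names)
        r = y - X @ fit.beta
        scale = np.median(np.abs(r - np.median(r))) / MAD_TO_SIGMA
        u = r / (BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        closed = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert np.max(np.abs(closed - fit.beta) / np.abs(closed)) < 1e-6

    def test_outlier_bounded_influence(self, rng):
        X, names = _design(rng, 100)
        y = 1.0 * X[:, 0] + rng.normal(0, 1, 100)
        base_irls = fit_bin(y, X, names).coef("age")
        base_ols = fit_bin(y, X, names, estimator="ols").coef("age")
        y_out = y.copy()
        y_out[0] += 500.0
        irls_shift = abs(fit_bin(y_out, X, names).coef("age") - base_irls)
        ols_shift = abs(
            fit_bin(y_out, X, names, estimator="ols").coef("age") - base_ols
        )
        assert irls_shift < ols_shift

    def test_rank_deficient_names_columns(self, rng):
        age = np.random.default_rng(0).uniform(16, 86, 30)
        with pytest.raises(RankDeficientError, match="age2"):
            make_design({"age": age, "age2": 2 * age})

    def test_too_few_rows(self):
        with pytest.raises(RankDeficientError, match="rows"):
            make_design({"a": [1.0, 2, 3], "b": [2.0, 1, 3], "c": [0.0, 1, 2]})

    def test_shift_equivariance(self, rng):
        X, names = _design(rng, 80)
        y = 0.3 * X[:, 0] + rng.normal(0, 1, 80)
        f0 = fit_bin(y, X, names)
        f1 = fit_bin(y + 10.0, X, names)
        assert f1.coef("age") == pytest.approx(f0.coef("age"), abs=1e-7)
        assert f1.coef("intercept") == pytest.approx(
            f0.coef("intercept") + 10.0, abs=1e-7
        )

    def test_scale_equivariance_t_invariant(self, rng):
        X, names = _design(rng, 80)
        y = 0.3 * X[:, 0] + rng.normal(0, 1, 80)
        f0 = fit_bin(y, X, names)
        f1 = fit_bin(3.0 * y, X, names)
        assert f1.coef("age") == pytest.approx(3.0 * f0.coef("age"), rel=1e-6)
        assert f1.tstat("age") == pytest.approx(f0.tstat("age"), rel=1e-6)
        assert f1.r2 == pytest.approx(f0.r2, rel=1e-6)

    def test_gender_identity(self, rng):
        X, names = _design(rng, 50)
        y = X[:, names.index("gender")].astype(float)
        fit = fit_bin(y, X, names)
        assert fit.coef("gender") == pytest.approx(1.0, abs=1e-8)
        assert fit.coef("age") == pytest.approx(0.0, abs=1e-8)

    def test_scalar_regression_sign_recovery(self, rng):
        # planted |effect|/sigma = 0.5 recovered in >= 95% of simulations
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            r = np.random.default_rng(s)
            X, names = _design(r, 100)
            age_z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
            y = -0.5 * age_z + r.normal(0, 1, 100)
            fit = scalar_robust_regression(y, X, names)
            hits += fit.coef("age") < 0
        assert hits >= 95

    def test_dof_guard(self):
        with pytest.raises(RankDeficientError):
            fit_bin(
                np.array([1.0, 2.0, 3.0]),
                np.column_stack(
                    [np.arange(3.0), np.arange(3.0) ** 2, np.ones(3)]
                ),
                ["a", "b", "c"],
            )


class TestMassUnivariate:
    def test_constant_column(self, rng):
        X, names = _design(rng, 40)
        Y = rng.normal(size=(40, 25))
        Y[:, 3] = 5.0
        st = mass_univariate(Y, X, names)
        assert st.beta[0].ravel()[3] == pytest.approx(0.0, abs=1e-10)
        assert st.r2.ravel()[3] == 0.0

    def test_planted_block_detected(self, rng):
        n = 80
        X, names = _design(rng, n)
        Y = rng.normal(0, 1.0, size=(n, 400))  # 20x20 grid
        age_c = X[:, 0] - X[:, 0].mean()
        block = np.zeros((20, 20), dtype=bool)
        block[3:8, 3:8] = True
        Y[:, block.ravel()] -= 0.05 * age_c[:, None]
        st = mass_univariate(Y, X, names)
        tmap = st.map("age", "t")
        assert tmap[block].mean() < -2
        i, j = np.unravel_index(np.argmax(np.abs(tmap)), tmap.shape)
        assert block[i, j]

    def test_permuted_ages_null(self, rng):
        n = 80
        X, names = _design(rng, n)
        Y = rng.normal(0, 1.0, size=(n, 400))
        st = mass_univariate(Y, X, names)
        # type-I at nominal level across the 400 independent null bins
        frac = np.mean(st.p[0] < 0.05)
        assert 0.01 < frac < 0.12

    def test_r2_nesting_with_ols(self, rng):
        n = 60
        r = np.random.default_rng(3)
        base = {"age": r.uniform(16, 86, n), "gender": r.integers(1, 3, n).astype(float)}
        Y = r.normal(size=(n, 25))
        X1, n1 = make_design(dict(base))
        X2, n2 = make_design({**base, "usage": r.normal(size=n)})
        st1 = mass_univariate(Y, X1, n1, estimator="ols")
        st2 = mass_univariate(Y, X2, n2, estimator="ols")
        assert np.all(st2.r2 >= st1.r2 - 1e-12)


class TestClusterCorrect:
    def test_planted_cluster_significant_noise_spikes_not(self, rng):
        n = 80
        X, names = _design(rng, n)
        Y = rng.normal(0, 1.0, size=(n, 2500))
        age_c = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
        block = np.zeros((50, 50), dtype=bool)
        block[10:18, 10:18] = True
        Y[:, block.ravel()] += 0.8 * age_c[:, None]
        st = mass_univariate(Y, X, names)
        res = cluster_correct(st, Y, X, "age", n_boot=100, alpha=0.05, seed=0)
        assert res.n_significant >= 1
        # the planted block is covered by significant bins
        assert (res.sig_mask & block).sum() >= 0.9 * block.sum()
        # significant bins outside the block are rare
        assert (res.sig_mask & ~block).sum() < 25

    def test_alpha_one_all_supra_clusters_significant(self, rng):
        n = 40
        X, names = _design(rng, n)
        Y = rng.normal(size=(n, 100))
        st = mass_univariate(Y, X, names)
        res = cluster_correct(st, Y, X, "age", n_boot=50, alpha=1.0, seed=1)
        assert all(c.significant for c in res.clusters)

    def test_refuses_tiny_n_boot(self, rng):
        X, names = _design(rng, 30)
        Y = rng.normal(size=(30, 100))
        st = mass_univariate(Y, X, names)
        with pytest.raises(ValueError, match="n_boot"):
            cluster_correct(st, Y, X, "age", n_boot=10)

    def test_masses_are_supra_sums(self, rng):
        n = 50
        X, names = _design(rng, n)
        Y = rng.normal(size=(n, 2500))
        st = mass_univariate(Y, X, names)
        res = cluster_correct(st, Y, X, "age", n_boot=30, alpha=0.05, seed=2)
        tsq = st.t[0] ** 2
        for c in res.clusters:
            assert c.mass == pytest.approx(
                tsq[c.bins[:, 0], c.bins[:, 1]].sum(), rel=1e-9
            )
            assert c.mass >= tsq[c.bins[:, 0], c.bins[:, 1]].min()

    def test_deterministic_given_seed(self, rng):
        n = 40
        X, names = _design(rng, n)
        Y = rng.normal(size=(n, 400))
        st = mass_univariate(Y, X, names)
        r1 = cluster_correct(st, Y, X, "age", n_boot=50, seed=9)
        r2 = cluster_correct(st, Y, X, "age", n_boot=50, seed=9)
        assert r1.mass_threshold == r2.mass_threshold
        assert np.array_equal(r1.sig_mask, r2.sig_mask)


class TestFdrCorrect:
    def test_bh_hand_computation(self):
        # 0.0001 <= (1/3)*0.05; 0.5 > (2/3)*0.05; 0.9 > 0.05
        mask = fdr_correct([0.0001, 0.5, 0.9], alpha=0.05)
        assert mask.tolist() == [True, False, False]

    def test_all_ones(self):
        assert not fdr_correct([1.0, 1.0, 1.0], alpha=0.05).any()

    def test_all_zeros(self):
        assert fdr_correct([0.0, 0.0], alpha=0.05).all()

    def test_empty(self):
        assert fdr_correct([], alpha=0.05).size == 0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        ours = fdr_correct(p, alpha=0.01)
        theirs = multipletests(p, alpha=0.01, method="fdr_bh")[0]
        assert np.array_equal(ours, theirs)
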