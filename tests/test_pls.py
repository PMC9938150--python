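"""PLS correlation: fit, permutation, bootstrap and loading inference."""

import math

import numpy as np
import pytest

from fcpls.pls import (behavior_loadings, bootstrap_reliability,
                       bsr_tail_probability, combined_seed_matrix,
                       combined_seed_model, cosine_similarity,
                       permutation_test, pls_fit, residualize, threshold_bsr,
                       zscore_columns)
from fcpls.simulate import simulate_pls_matrices


class TestResidualize:
    def test_orthogonal_column_unchanged(self, rng):
        conf = rng.normal(size=(50, 2))
        col = rng.normal(size=50)
        col -= col.mean()
        design = np.column_stack([np.ones(50), conf])
        col -= design @ np.linalg.lstsq(design, col, rcond=None)[0]
        np.testing.assert_allclose(residualize(col, conf), col, atol=1e-10)

    def test_exact_combination_goes_to_zero(self, rng):
        conf = rng.normal(size=(30, 3))
        col = conf @ np.array([2.0, -1.0, 0.5]) + 4.0
        np.testing.assert_allclose(residualize(col, conf), 0.0, atol=1e-10)

    def test_signal_recovered_noise_free(self, rng):
        conf = rng.normal(size=(40, 1))
        signal = rng.normal(size=40)
        signal = residualize(signal, conf)  # make signal confound-free
        data = 2.0 * conf[:, 0] + signal
        r = np.corrcoef(residualize(data, conf), signal)[0, 1]
        assert r > 0.99

    def test_residuals_orthogonal_to_confounds(self, rng):
        conf = rng.normal(size=(25, 4))
        resid = residualize(rng.normal(size=(25, 6)), conf)
        np.testing.assert_allclose(conf.T @ resid, 0.0, atol=1e-8)
        np.testing.assert_allclose(resid.mean(0), 0.0, atol=1e-10)

    def test_too_many_confounds_rejected(self, rng):
        with pytest.raises(ValueError):
            residualize(rng.normal(size=(5, 2)), rng.normal(size=(5, 5)))


class TestZScore:
    def test_closed_form(self):
        np.testing.assert_allclose(zscore_columns(np.array([[1.0], [2.0], [3.0]])),
                                   [[-1.0], [0.0], [1.0]])

    def test_idempotent(self, rng):
        z = zscore_columns(rng.normal(size=(20, 4)))
        np.testing.assert_allclose(zscore_columns(z), z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        m = np.ones((5, 2))
        m[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="MoCA"):
            zscore_columns(m, names=["UPSIT", "MoCA"])


class TestPLSFit:
    def test_single_behavior_closed_form(self, rng):
        X = zscore_columns(rng.normal(size=(30, 12)))
        y = zscore_columns(rng.normal(size=(30, 1)))
        model = pls_fit(X, y, zscore=False)
        r = X.T @ y[:, 0]
        assert model.S[0] == pytest.approx(np.linalg.norm(r), abs=1e-10)
        assert abs(cosine_similarity(model.V[:, 0], r)) == pytest.approx(1.0, abs=1e-10)
        assert model.explained_covariance[0] == pytest.approx(1.0)

    def test_top_singular_value_matches_power_iteration(self, rng):
        # independent oracle: power iteration on R^T R
        for _ in range(20):
            X = zscore_columns(rng.normal(size=(21, 20)))
            Y = zscore_columns(rng.normal(size=(21, 5)))
            model = pls_fit(X, Y, zscore=False)
            R = X.T @ Y
            v = rng.normal(size=5)
            for _ in range(3000):
                v = R.T @ (R @ v)
                v /= np.linalg.norm(v)
            s1 = np.linalg.norm(R @ v)
            assert model.S[0] == pytest.approx(s1, abs=1e-8)

    def test_squared_singular_values_sum_to_frobenius(self, rng):
        X, Y, _ = simulate_pls_matrices(40, 30, 6, 0.4, rng=rng)
        model = pls_fit(X, Y)
        R = model.X.T @ model.Y
        assert (model.S**2).sum() == pytest.approx((R**2).sum(), rel=1e-10)
        assert model.explained_covariance.sum() == pytest.approx(1.0)

    def test_orthonormal_saliences(self, rng):
        X, Y, _ = simulate_pls_matrices(50, 25, 8, 0.5, rng=rng)
        model = pls_fit(X, Y)
        L = model.n_lv
        np.testing.assert_allclose(model.U.T @ model.U, np.eye(L), atol=1e-8)
        np.testing.assert_allclose(model.V.T @ model.V, np.eye(L), atol=1e-8)

    def test_first_lv_maximizes_score_covariance(self, rng):
        X, Y, _ = simulate_pls_matrices(40, 15, 5, 0.5, rng=rng)
        model = pls_fit(X, Y)
        best = np.cov(model.Lx[:, 0], model.Ly[:, 0])[0, 1]
        for _ in range(10_000):
            v = rng.normal(size=15)
            u = rng.normal(size=5)
            v /= np.linalg.norm(v)
            u /= np.linalg.norm(u)
            assert np.cov(model.X @ v, model.Y @ u)[0, 1] <= best + 1e-10

    def test_rank1_link_recovery(self, rng):
        X, Y, truth = simulate_pls_matrices(80, 200, 10, 0.5, rng=rng)
        model = pls_fit(X, Y)
        assert abs(cosine_similarity(model.V[:, 0], truth["v_star"])) >= 0.9
        assert abs(cosine_similarity(model.U[:, 0], truth["u_star"])) >= 0.9

    def test_mismatched_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.normal(size=(10, 3)), rng.normal(size=(11, 2)))


class TestPermutation:
    def test_noise_free_link_attains_minimum_p(self, rng):
        g = rng.normal(size=30)
        X = np.outer(g, rng.normal(size=20))
        X += rng.normal(0, 1e-6, X.shape)  # break exact rank deficiency
        Y = np.outer(g, rng.normal(size=4)) + rng.normal(0, 1e-6, (30, 4))
        model = pls_fit(X, Y)
        res = permutation_test(model, n_perm=99, seed=0)
        assert res.p_values[0] == pytest.approx(1 / 100)

    def test_p_never_zero_and_deterministic(self, rng):
        X, Y, _ = simulate_pls_matrices(25, 10, 3, 0.0, rng=rng)
        model = pls_fit(X, Y)
        a = permutation_test(model, n_perm=50, seed=42)
        b = permutation_test(model, n_perm=50, seed=42)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.null_singular, b.null_singular)
        assert (a.p_values > 0).all()

    def test_null_p_roughly_uniform(self, rng):
        # light calibration check; the full one runs in the acceptance suite
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            X, Y, _ = simulate_pls_matrices(30, 20, 4, 0.0, rng=rng)
            model = pls_fit(X, Y)
            p = permutation_test(model, n_perm=99, seed=i).p_values[0]
            hits += p < 0.05
        assert 0.0 <= hits / n_rep <= 0.12

    def test_invalid_n_perm(self, rng):
        X, Y, _ = simulate_pls_matrices(10, 4, 2, 0.0, rng=rng)
        with pytest.raises(ValueError):
            permutation_test(pls_fit(X, Y), n_perm=0)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        X, Y, _ = simulate_pls_matrices(30, 15, 4, 0.5, rng=rng)
        model = pls_fit(X, Y)
        a = bootstrap_reliability(model, n_boot=50, seed=7)
        b = bootstrap_reliability(model, n_boot=50, seed=7)
        np.testing.assert_array_equal(a.bsr, b.bsr)

    def test_salient_voxels_have_large_bsr(self, rng):
        X, Y, truth = simulate_pls_matrices(80, 100, 8, 0.6, rng=rng)
        model = pls_fit(X, Y)
        boot = bootstrap_reliability(model, n_boot=200, seed=1)
        salient = truth["v_star"] != 0
        assert np.median(np.abs(boot.bsr[salient, 0])) > 5
        # zero-salience voxels mostly below the 3.3 cutoff
        assert (np.abs(boot.bsr[~salient, 0]) < 3.3).mean() > 0.95

    def test_degenerate_replicates_abort(self, rng):
        # a column that is constant except for one subject collapses to a
        # constant in ~1/3 of resamples, exceeding the redraw budget
        X = np.column_stack([np.eye(6)[:, 0], rng.normal(size=6)])
        Y = np.column_stack([np.eye(6)[:, 1], rng.normal(size=6)])
        model = pls_fit(X, Y)
        with pytest.raises(RuntimeError, match="degenerate"):
            bootstrap_reliability(model, n_boot=200, seed=0)

    def test_invalid_n_boot(self, rng):
        X, Y, _ = simulate_pls_matrices(10, 4, 2, 0.0, rng=rng)
        with pytest.raises(ValueError):
            bootstrap_reliability(pls_fit(X, Y), n_boot=1)


class TestThresholdBSR:
    def test_two_sided_boundary(self):
        bsr = np.array([3.4, -3.4, 3.3, -3.3, 3.29, 0.0])
        np.testing.assert_array_equal(threshold_bsr(bsr, 3.3),
                                      [True, True, True, True, False, False])

    def test_tail_probability_consistent_with_erf_oracle(self):
        p = bsr_tail_probability(3.3)
        oracle = 1.0 - math.erf(3.3 / math.sqrt(2.0))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p < 0.001


class TestBehaviorLoadings:
    def test_linked_behavior_significant(self, rng):
        X, _, truth = simulate_pls_matrices(60, 40, 1, 0.0, rng=rng)
        model0 = pls_fit(X, rng.normal(size=(60, 1)))
        score = model0.Lx[:, 0]
        Y = np.column_stack([score + rng.normal(0, 0.3 * score.std(), 60),
                             rng.normal(size=60)])
        model = pls_fit(X, Y, behavior_names=["linked", "noise"])
        boot = bootstrap_reliability(model, n_boot=200, seed=3)
        loads = behavior_loadings(model, boot, lv=0)
        linked = loads.behavior_names.index("linked")
        assert loads.correlation[linked] > 0.8
        assert loads.significant[linked]
        assert loads.ci_low[linked] > 0

    def test_crossing_zero_rule(self, rng):
        X, Y, _ = simulate_pls_matrices(40, 20, 3, 0.5, rng=rng)
        model = pls_fit(X, Y)
        boot = bootstrap_reliability(model, n_boot=100, seed=5)
        loads = behavior_loadings(model, boot, lv=0)
        for lo, hi, sig in zip(loads.ci_low, loads.ci_high, loads.significant):
            assert sig == ((lo > 0) or (hi < 0))

    def test_independent_behavior_ci_contains_zero_usually(self, rng):
        covered = 0
        for i in range(20):
            X = rng.normal(size=(50, 30))
            Y = np.column_stack([rng.normal(size=50), rng.normal(size=50)])
            model = pls_fit(X, Y)
            boot = bootstrap_reliability(model, n_boot=100, seed=i)
            loads = behavior_loadings(model, boot, lv=0)
            covered += int(not loads.significant.all())
        assert covered >= 15

    def test_lv_out_of_range(self, rng):
        X, Y, _ = simulate_pls_matrices(20, 8, 2, 0.0, rng=rng)
        model = pls_fit(X, Y)
        boot = bootstrap_reliability(model, n_boot=10, seed=0)
        with pytest.raises(ValueError):
            behavior_loadings(model, boot, lv=5)


class TestCombinedSeedModel:
    def test_feature_counts_and_owner_labels(self, rng):
        xs = {"a": rng.normal(size=(20, 5)), "b": rng.normal(size=(20, 5))}
        X, owner = combined_seed_matrix(xs)
        assert X.shape == (20, 10)
        assert list(owner) == ["a"] * 5 + ["b"] * 5

    def test_concatenation_order_preserves_singular_values(self, rng):
        xs = {"a": rng.normal(size=(25, 6)), "b": rng.normal(size=(25, 4))}
        Y = rng.normal(size=(25, 3))
        m1 = combined_seed_model(xs, Y)
        m2 = combined_seed_model({"b": xs["b"], "a": xs["a"]}, Y)
        np.testing.assert_allclose(m1.S, m2.S, atol=1e-10)

    def test_per_seed_salience_blocks_recovered(self, rng):
        g = rng.normal(size=100)
        xs, v_true = {}, {}
        for name in ("a", "b"):
            v = rng.normal(size=30)
            v /= np.linalg.norm(v)
            xs[name] = 4.0 * np.outer(g, v) + rng.normal(size=(100, 30))
            v_true[name] = v
        Y = 2.0 * np.outer(g, np.ones(5) / np.sqrt(5)) + rng.normal(size=(100, 5))
        model = combined_seed_model(xs, Y)
        for name in ("a", "b"):
            block = model.V[model.feature_seed == name, 0]
            assert abs(cosine_similarity(block, v_true[name])) >= 0.8

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            combined_seed_matrix({"a": rng.normal(size=(10, 2)),
                                  "b": rng.normal(size=(11, 2))})
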