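"""Multiplicative-update NMF and the joint shared-subspace factorization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmftl.nmf import (
    FitConfig,
    SharedSubspaceNMF,
    fit_shared_subspace,
    joint_objective,
    load_subspace_model,
    nmf_factorize,
    project_shared,
    save_subspace_model,
)


class TestPlainNMF:
    def test_rank_one_matrix_factorized_exactly(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0]])
        res = nmf_factorize(A, r=1, config=FitConfig(r=1, max_iter=500, eps=1e-12))
        assert res.objective_trace[-1] < 1e-8

    def test_exact_factorization_is_a_fixed_point(self, rng):
        U0 = rng.uniform(0.5, 1.0, (5, 2))
        V0 = rng.uniform(0.5, 1.0, (2, 4))
        A = U0 @ V0
        res = nmf_factorize(
            A, r=2, config=FitConfig(r=2, max_iter=1, eps=1e-30), init=(U0, V0)
        )
        np.testing.assert_allclose(res.U, U0, rtol=1e-9)
        np.testing.assert_allclose(res.V, V0, rtol=1e-9)

    def test_planted_low_rank_recovered(self, rng):
        A = rng.uniform(0.1, 1.0, (6, 2)) @ rng.uniform(0.1, 1.0, (2, 5))
        res = nmf_factorize(A, r=2, config=FitConfig(r=2, max_iter=2000, eps=1e-12))
        assert res.objective_trace[-1] / np.linalg.norm(A) ** 2 < 1e-6

    def test_trace_non_increasing_and_factors_nonneg(self, rng):
        A = rng.uniform(0, 1, (15, 9))
        res = nmf_factorize(A, r=3, config=FitConfig(r=3, max_iter=300, eps=1e-12))
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])
        assert np.all(res.U >= 0) and np.all(res.V >= 0)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            nmf_factorize(np.array([[1.0, -1.0]]), r=1)
        with pytest.raises(ValueError, match="out of range"):
            nmf_factorize(np.ones((3, 3)), r=4)


class TestJointObjective:
    def test_exact_reconstruction_gives_zero(self, planted):
        Xs, Xt, (Ws, Wt, H) = planted(seed=0)
        assert joint_objective(Xs, Xt, Ws, Wt, H, 0.5) == pytest.approx(0.0, abs=1e-18)

    def test_equal_residuals_convex_combination(self):
        Xs = np.array([[1.0, 0.0]])
        Xt = np.array([[1.0, 0.0]])
        W = np.array([[0.0]])
        H = np.array([[0.0, 0.0]])
        # both residual norms equal 1 -> objective 1 for any alpha
        for alpha in (0.2, 0.5, 0.9):
            assert joint_objective(Xs, Xt, W, W, H, alpha) == pytest.approx(1.0)

    def test_matches_naive_entry_loop(self, rng):
        Xs, Xt = rng.random((7, 5)), rng.random((4, 5))
        Ws, Wt, H = rng.random((7, 3)), rng.random((4, 3)), rng.random((3, 5))
        got = joint_objective(Xs, Xt, Ws, Wt, H, 0.3)
        expected = 0.0
        for X, W, a in ((Xs, Ws, 0.3), (Xt, Wt, 0.7)):
            R = X - W @ H
            for i in range(R.shape[0]):
                for j in range(R.shape[1]):
                    expected += a * R[i, j] ** 2
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            joint_objective(
                rng.random((3, 4)), rng.random((2, 5)),
                rng.random((3, 2)), rng.random((2, 2)), rng.random((2, 4)),
            )


class TestJointFactorization:
    def test_identical_domains_reduce_to_plain_nmf(self, rng):
        X = rng.uniform(0, 1, (20, 8))
        W0 = rng.uniform(0.1, 1.1, (20, 3))
        H0 = rng.uniform(0.1, 1.1, (3, 8))
        cfg = FitConfig(r=3, alpha_s=0.5, max_iter=100, eps=1e-30)
        joint = fit_shared_subspace(X, X, cfg, init=(W0, W0.copy(), H0))
        plain = nmf_factorize(X, 3, cfg, init=(W0, H0))
        np.testing.assert_allclose(
            joint.objective_trace, plain.objective_trace, atol=1e-10
        )
        np.testing.assert_allclose(joint.Ws, joint.Wt, atol=0)

    def test_planted_instance_driven_to_zero(self, planted):
        Xs, Xt, _ = planted(seed=7)
        m = fit_shared_subspace(
            Xs, Xt, FitConfig(r=3, max_iter=2000, eps=1e-12, seed=7)
        )
        rel = m.objective_trace[-1] / (
            np.linalg.norm(Xs) ** 2 + np.linalg.norm(Xt) ** 2
        )
        assert rel < 1e-6

    def test_trace_monotone_and_factors_nonneg(self, rng):
        Xs, Xt = rng.uniform(0, 1, (25, 10)), rng.uniform(0, 1, (15, 10))
        m = fit_shared_subspace(Xs, Xt, FitConfig(r=4, max_iter=300, eps=1e-12))
        trace = m.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])
        for M in (m.H, m.Ws, m.Wt):
            assert np.all(M >= 0)

    def test_diagonal_rescaling_leaves_objective_unchanged(self, rng):
        Xs, Xt = rng.uniform(0, 1, (12, 6)), rng.uniform(0, 1, (9, 6))
        m = fit_shared_subspace(Xs, Xt, FitConfig(r=3, max_iter=50, eps=1e-12))
        D = np.diag(rng.uniform(0.5, 2.0, 3))
        base = joint_objective(Xs, Xt, m.Ws, m.Wt, m.H, m.alpha_s)
        scaled = joint_objective(
            Xs, Xt, m.Ws @ D, m.Wt @ D, np.linalg.inv(D) @ m.H, m.alpha_s
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_subspace_recovery_on_noiseless_planted_data(self, planted):
        cosines = []
        for seed in range(3):
            Xs, Xt, (_, _, Htrue) = planted(seed=seed, r=3)
            m = fit_shared_subspace(
                Xs, Xt, FitConfig(r=3, max_iter=2000, eps=1e-12, seed=seed)
            )
            Hf = m.H / np.linalg.norm(m.H, axis=1, keepdims=True)
            Ht = Htrue / np.linalg.norm(Htrue, axis=1, keepdims=True)
            cosines.append((Hf @ Ht.T).max(axis=1).mean())
        assert np.mean(cosines) >= 0.95

    def test_dimension_mismatch_and_negativity_rejected(self, rng):
        with pytest.raises(ValueError, match="share the feature space"):
            fit_shared_subspace(rng.random((5, 4)), rng.random((5, 3)))
        with pytest.raises(ValueError, match="non-negative"):
            fit_shared_subspace(-rng.random((5, 4)), rng.random((5, 4)))

    def test_stop_rule_any_stops_no_later_than_max(self, rng):
        Xs, Xt = rng.uniform(0, 1, (10, 6)), rng.uniform(0, 1, (8, 6))
        any_rule = fit_shared_subspace(
            Xs, Xt, FitConfig(r=2, max_iter=500, eps=1e-4, stop_rule="any")
        )
        max_rule = fit_shared_subspace(
            Xs, Xt, FitConfig(r=2, max_iter=500, eps=1e-4, stop_rule="max")
        )
        assert any_rule.iterations_run <= max_rule.iterations_run

    def test_serialization_round_trip(self, tmp_path, planted):
        Xs, Xt, _ = planted(seed=1)
        m = fit_shared_subspace(Xs, Xt, FitConfig(r=3, max_iter=50, eps=1e-12))
        save_subspace_model(m, tmp_path / "model")
        back = load_subspace_model(tmp_path / "model")
        np.testing.assert_allclose(back.H, m.H, rtol=1e-15)
        np.testing.assert_allclose(back.objective_trace, m.objective_trace)
        assert back.alpha_s == m.alpha_s


class TestProjection:
    def test_coordinate_selection(self):
        H = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_array_equal(
            project_shared(H, np.array([[1.0, 2.0, 0.0]])), [[1.0, 2.0]]
        )

    def test_zero_basis_gives_zero_projection(self, rng):
        out = project_shared(np.zeros((2, 5)), rng.random((4, 5)))
        np.testing.assert_array_equal(out, np.zeros((4, 2)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_per_row_matvec(self, seed):
        gen = np.random.default_rng(seed)
        H, X = gen.random((3, 6)), gen.random((5, 6))
        out = project_shared(H, X)
        for i in range(5):
            np.testing.assert_allclose(out[i], H @ X[i], rtol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            project_shared(rng.random((2, 4)), rng.random((3, 5)))


class TestSharedSubspaceEstimator:
    def test_fit_transform_api(self, planted):
        Xs, Xt, _ = planted(seed=2)
        est = SharedSubspaceNMF(r=3, max_iter=200, eps=1e-12, random_state=0)
        est.fit(Xs, X_target=Xt)
        assert est.H_.shape == (3, Xs.shape[1])
        np.testing.assert_allclose(est.transform(Xs), Xs @ est.H_.T)
        params = est.get_params()
        assert params["r"] == 3 and params["alpha_s"] == 0.5

    def test_requires_target_domain(self, planted):
        Xs, _, _ = planted(seed=2)
        with pytest.raises(ValueError, match="target"):
            SharedSubspaceNMF(r=2).fit(Xs)
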