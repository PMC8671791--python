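"""Sparse factorization: coding oracles, dictionary updates, full fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sccdyn as sd
from sccdyn.decomposition import factor_objective


def soft(x, lam):
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


class TestLassoCode:
    def test_single_atom_closed_form(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(20)
        t /= np.linalg.norm(t)
        s = t * 1.0  # t's = 1.0 exactly
        c = sd.lasso_code(s[:, None], t[:, None], lambda_=0.1)
        np.testing.assert_allclose(c, [[0.9]], atol=1e-10)

    def test_orthonormal_dictionary_soft_threshold(self, rng):
        # for D with orthonormal columns the LASSO solution is coordinatewise
        # soft thresholding of D's
        D, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        S = rng.standard_normal((30, 7))
        C = sd.lasso_code(S, D, lambda_=0.3)
        np.testing.assert_allclose(C, soft(D.T @ S, 0.3), atol=1e-6)

    def test_full_shrinkage_above_max_correlation(self, rng):
        D = rng.standard_normal((15, 3))
        S = rng.standard_normal((15, 4))
        lam = np.abs(D.T @ S).max() + 1e-9
        np.testing.assert_array_equal(sd.lasso_code(S, D, lam), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_variable_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.standard_normal((10, 2))
        s = rng.standard_normal(10)
        lam = 0.2
        c = sd.lasso_code(s[:, None], D, lam)[:, 0]
        grid = np.linspace(-3, 3, 601)
        g1, g2 = np.meshgrid(grid, grid, indexing="ij")
        cand = np.stack([g1.ravel(), g2.ravel()])
        resid = s[:, None] - D @ cand
        obj = 0.5 * np.sum(resid**2, axis=0) + lam * np.sum(
            np.abs(cand), axis=0
        )
        best = cand[:, np.argmin(obj)]
        assert np.all(np.abs(c - best) <= 0.011)  # grid spacing 0.01
        # and our objective cannot exceed the grid optimum
        mine = 0.5 * np.sum((s - D @ c) ** 2) + lam * np.sum(np.abs(c))
        assert mine <= obj.min() + 1e-4

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10**6))
    def test_kkt_conditions(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.standard_normal((12, 4))
        S = rng.standard_normal((12, 3))
        lam = 0.15
        C = sd.lasso_code(S, D, lam)
        grad = D.T @ (D @ C - S)
        on = C != 0
        assert np.all(np.abs(grad[on] + lam * np.sign(C[on])) < 1e-6)
        assert np.all(np.abs(grad[~on]) <= lam + 1e-6)

    def test_matches_sklearn_lasso(self, rng):
        from sklearn.linear_model import Lasso

        D = rng.standard_normal((25, 6))
        S = rng.standard_normal((25, 4))
        lam = 0.2
        C = sd.lasso_code(S, D, lam)
        ref = Lasso(alpha=lam / 25, fit_intercept=False, tol=1e-12,
                    max_iter=100000).fit(D, S).coef_.T
        np.testing.assert_allclose(C, ref, atol=1e-6)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            sd.lasso_code(rng.standard_normal((5, 1)),
                          rng.standard_normal((5, 2)), -0.1)

    def test_sparsity_nondecreasing_in_lambda(self, rng):
        D = rng.standard_normal((20, 5))
        S = rng.standard_normal((20, 10))
        zeros = [
            np.mean(sd.lasso_code(S, D, lam) == 0)
            for lam in (0.01, 0.1, 0.5, 2.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(zeros, zeros[1:]))


class TestDictionaryUpdate:
    def test_rank_one_closed_form(self, rng):
        c = rng.standard_normal(8)[None, :]
        S = rng.standard_normal((10, 8))
        T0 = rng.standard_normal((10, 1))
        T, dead = sd.dictionary_update(S, c, T0)
        opt = S @ c[0] / (c[0] @ c[0])
        if np.linalg.norm(opt) > 1:
            opt /= np.linalg.norm(opt)
        np.testing.assert_allclose(T[:, 0], opt, atol=1e-10)
        assert not dead.any()

    def test_orthogonal_rows_independent_regressions(self, rng):
        C = np.zeros((3, 9))
        C[0, :3] = rng.standard_normal(3)
        C[1, 3:6] = rng.standard_normal(3)
        C[2, 6:] = rng.standard_normal(3)
        S = rng.standard_normal((12, 9))
        T0 = rng.standard_normal((12, 3))
        T, _ = sd.dictionary_update(S, C, T0)
        for j in range(3):
            opt = S @ C[j] / (C[j] @ C[j])
            if np.linalg.norm(opt) > 1:
                opt /= np.linalg.norm(opt)
            np.testing.assert_allclose(T[:, j], opt, atol=1e-8)

    def test_unit_ball_constraint(self, rng):
        C = rng.standard_normal((4, 20))
        S = 50 * rng.standard_normal((15, 20))
        T, _ = sd.dictionary_update(S, C, rng.standard_normal((15, 4)))
        assert np.all(np.linalg.norm(T, axis=0) ** 2 <= 1 + 1e-9)

    def test_objective_not_increased(self, rng):
        C = rng.standard_normal((3, 15))
        S = rng.standard_normal((20, 15))
        T0 = rng.standard_normal((20, 3))
        T0 /= np.maximum(np.linalg.norm(T0, axis=0), 1.0)
        before = factor_objective(S, T0, C, 0.0)
        T, _ = sd.dictionary_update(S, C, T0)
        assert factor_objective(S, T, C, 0.0) <= before + 1e-12

    def test_dead_atom_flagged_and_unchanged(self, rng):
        C = np.vstack([rng.standard_normal(10), np.zeros(10)])
        S = rng.standard_normal((8, 10))
        T0 = rng.standard_normal((8, 2))
        T, dead = sd.dictionary_update(S, C, T0)
        assert dead.tolist() == [False, True]
        np.testing.assert_array_equal(T[:, 1], T0[:, 1])


class TestLearnGroupSccs:
    def test_planted_recovery(self, small_truth, small_stack, small_fit):
        rep = sd.match_components(small_truth.C_true, small_fit.C)
        assert np.median(rep.matched_eta2) >= 0.9
        signal = np.vstack(
            [small_truth.noiseless_stack(i)
             for i in range(small_truth.n_subjects)]
        )
        rec = small_fit.T @ small_fit.C
        err = np.linalg.norm(rec - signal) / np.linalg.norm(signal)
        assert err <= 0.05

    def test_unpenalized_full_rank_exact(self, rng):
        S = rng.standard_normal((12, 6))  # rank 6
        dec = sd.learn_group_sccs(S, k=6, lambda_=0.0, seed=0, max_iter=500,
                                  tol=1e-12)
        err = np.linalg.norm(S - dec.T @ dec.C) / np.linalg.norm(S)
        assert err <= 1e-6

    def test_objective_trace_monotone(self, small_fit):
        tr = np.array(small_fit.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_rows_ranked_by_norm(self, small_fit):
        norms = small_fit.row_norms
        assert np.all(np.diff(norms) <= 1e-12)

    def test_unit_ball_atoms(self, small_fit):
        assert np.all(np.linalg.norm(small_fit.T, axis=0) ** 2 <= 1 + 1e-9)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            sd.learn_group_sccs(rng.standard_normal((5, 8)), k=6,
                                lambda_=0.1)

    def test_determinism(self, small_stack):
        a = sd.learn_group_sccs(small_stack, k=2, lambda_=0.05, seed=3)
        b = sd.learn_group_sccs(small_stack, k=2, lambda_=0.05, seed=3)
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.T, b.T)

    def test_recovery_improves_with_snr(self):
        # matched similarity to the planted truth rises over an SNR grid
        med = []
        for snr in (0.5, 5.0, 50.0):
            vals = []
            for seed in range(5):
                truth = sd.make_ground_truth(
                    n_rois=12, n_networks=4, k_star=3, sparsity=0.2,
                    n_subjects=6, w=24, target_snr=snr, seed=seed,
                )
                stack = sd.concatenate_subjects(sd.synth_windowed_stack(truth))
                dec = sd.learn_group_sccs(stack, k=3, lambda_=0.02, seed=seed)
                vals.append(np.median(
                    sd.match_components(truth.C_true, dec.C).matched_eta2
                ))
            med.append(np.median(vals))
        assert med[0] < med[1] <= med[2] + 1e-12


class TestSubjectCoding:
    def test_slice_coding_beats_group_block_error(self, small_truth,
                                                  small_stacks, small_stack,
                                                  small_fit):
        # refitting C per subject cannot do worse than the shared C on that
        # subject's block (same dictionary block, more freedom)
        i = 0
        t_i = small_fit.subject_temporal(small_stack, i)
        dec_i = sd.code_subject(small_stacks[i], t_i, small_fit.lambda_)
        block = small_stack.subject_block(i)
        err_subj = factor_objective(block, t_i, dec_i.C_i, small_fit.lambda_)
        err_group = factor_objective(block, t_i, small_fit.C,
                                     small_fit.lambda_)
        assert err_subj <= err_group + 1e-9

    def test_huge_lambda_zero_code(self, small_stacks, small_stack,
                                   small_fit):
        t_i = small_fit.subject_temporal(small_stack, 0)
        dec = sd.code_subject(small_stacks[0], t_i, 1e9)
        np.testing.assert_array_equal(dec.C_i, 0.0)
        np.testing.assert_array_equal(sd.reconstruct(dec), 0.0)

    def test_reconstruct_shape_and_zero(self, small_stacks, small_stack,
                                        small_fit):
        t_i = small_fit.subject_temporal(small_stack, 1)
        dec = sd.code_subject(small_stacks[1], t_i, small_fit.lambda_)
        rec = sd.reconstruct(dec)
        assert rec.shape == small_stacks[1].data.shape
        np.testing.assert_allclose(rec, dec.T_i @ dec.C_i)

    def test_window_mismatch_rejected(self, small_stacks, small_fit):
        with pytest.raises(ValueError, match="windows"):
            sd.code_subject(small_stacks[0], small_fit.T[:5], 0.1)


class TestRankAndSigns:
    def test_rank_sorts_by_row_norm(self):
        C = np.diag([1.0, 3.0, 2.0]) @ np.ones((3, 4))
        T = np.eye(4)[:, :3]
        dec = sd.GroupDecomposition(T=T.copy(), C=C.copy(), k=3,
                                    lambda_=0.1, seed=0)
        prod = dec.T @ dec.C
        sd.rank_components(dec)
        np.testing.assert_allclose(dec.row_norms, [6.0, 4.0, 2.0])
        np.testing.assert_array_equal(dec.T @ dec.C, prod)

    def test_equal_norms_stable(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.eye(2)
        dec = sd.GroupDecomposition(T=T, C=C, k=2, lambda_=0.1, seed=0)
        sd.rank_components(dec)
        np.testing.assert_array_equal(dec.C, np.eye(2))

    def test_sign_flip(self):
        C = np.array([[-1.0, -2.0], [1.0, 2.0], [1.0, -1.0]])
        T = np.arange(6.0).reshape(2, 3)
        dec = sd.GroupDecomposition(T=T.copy(), C=C.copy(), k=3,
                                    lambda_=0.1, seed=0)
        prod = dec.T @ dec.C
        sd.canonicalize_signs(dec)
        np.testing.assert_array_equal(dec.C[0], [1.0, 2.0])  # flipped
        np.testing.assert_array_equal(dec.C[1], [1.0, 2.0])  # untouched
        np.testing.assert_array_equal(dec.C[2], [1.0, -1.0])  # zero-sum rule
        np.testing.assert_allclose(dec.T @ dec.C, prod, atol=1e-12)
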