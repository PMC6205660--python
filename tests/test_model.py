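import numpy as np
import pytest

import clonalprof as cp
from clonalprof import model as M
from clonalprof.external import InputTensor, ProfileSourceSpec


def single_position_instance(x_row, source_rows, y_row=None, pos=1):
    """One CF, one defined position, p sources built from explicit rows."""
    n_src = len(source_rows)
    xf = np.zeros((1, cp.N_POSITIONS, cp.N_AA))
    defined = np.zeros((1, cp.N_POSITIONS), dtype=bool)
    xf[0, pos - 1] = x_row
    defined[0, pos - 1] = True
    x = cp.ProfileTensor(xf, defined.copy(), ("cf",))
    vals = np.zeros((1, cp.N_POSITIONS, cp.N_AA, n_src))
    for l, row in enumerate(source_rows):
        vals[0, pos - 1, :, l] = row
    specs = tuple(ProfileSourceSpec("custom", label=f"s{l}")
                  for l in range(n_src))
    xstar = InputTensor(vals, specs, defined.copy())
    y = None
    if y_row is not None:
        yf = np.zeros_like(xf)
        yf[0, pos - 1] = y_row
        y = cp.ProfileTensor(yf, defined.copy(), ("cf",))
    return x, xstar, y


def row(**freqs):
    out = np.zeros(cp.N_AA)
    for aa, v in freqs.items():
        out[cp.AA_LETTERS.index(aa)] = v
    return out


class TestPredict:
    def test_alpha_zero_is_baseline(self, small_dataset):
        ds = small_dataset
        w = cp.WeightMatrix.zeros(ds.xstar.p)
        yhat = cp.predict(ds.x, ds.xstar, w)
        np.testing.assert_array_equal(yhat.freqs, ds.x.freqs)

    def test_alpha_one_returns_source(self, small_dataset):
        ds = small_dataset
        xstar = ds.xstar.subset_sources([0])
        w = cp.WeightMatrix(np.ones((cp.N_POSITIONS, 1)))
        yhat = cp.predict(ds.x, xstar, w)
        np.testing.assert_allclose(yhat.freqs[yhat.defined],
                                   xstar.values[:, :, :, 0][yhat.defined])

    def test_quarter_weights_arithmetic(self):
        x, xstar, _ = single_position_instance(
            row(A=1.0), [row(C=1.0), row(D=1.0)])
        w = cp.WeightMatrix(np.full((cp.N_POSITIONS, 2), 0.25))
        yhat = cp.predict(x, xstar, w)
        expected = row(A=0.5, C=0.25, D=0.25)
        np.testing.assert_allclose(yhat.freqs[0, 0], expected)

    def test_rows_stay_on_simplex(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(3)
        raw = rng.random((cp.N_POSITIONS, ds.xstar.p))
        raw /= raw.sum(axis=1, keepdims=True) + 1.0
        yhat = cp.predict(ds.x, ds.xstar, cp.WeightMatrix(raw))
        assert np.all(yhat.freqs >= -1e-12)
        np.testing.assert_allclose(yhat.freqs[yhat.defined].sum(axis=1), 1.0)

    def test_infeasible_weights_rejected(self, small_dataset):
        ds = small_dataset
        bad = cp.WeightMatrix(np.full((cp.N_POSITIONS, ds.xstar.p), 0.9))
        with pytest.raises(ValueError):
            cp.predict(ds.x, ds.xstar, bad)


class TestL2Error:
    def test_identical_zero(self, small_dataset):
        assert cp.l2_error(small_dataset.y, small_dataset.y) == 0.0

    def test_single_position_arithmetic(self):
        x, xstar, y = single_position_instance(
            row(A=1.0), [row(C=1.0)], y_row=row(A=0.5, C=0.5))
        yhat = cp.predict(x, xstar, cp.WeightMatrix.zeros(1))
        assert cp.l2_error(y, yhat) == pytest.approx(0.5 / 149)

    def test_symmetry(self, small_dataset):
        ds = small_dataset
        w = cp.WeightMatrix(np.full((cp.N_POSITIONS, ds.xstar.p), 0.2))
        yhat = cp.predict(ds.x, ds.xstar, w)
        assert cp.l2_error(ds.y, yhat) == pytest.approx(cp.l2_error(yhat, ds.y))

    def test_mask_mismatch_rejected(self, small_dataset):
        ds = small_dataset
        other = cp.ProfileTensor(ds.y.freqs.copy(),
                                 np.zeros_like(ds.y.defined), ds.y.cf_ids)
        with pytest.raises(ValueError):
            cp.l2_error(ds.y, other)


class TestDiffOperatorAndPenalty:
    def test_first_difference(self):
        np.testing.assert_allclose(cp.diff_operator([0.1, 0.3, 0.2], 1),
                                   [0.2, -0.1])

    def test_second_difference(self):
        np.testing.assert_allclose(cp.diff_operator([1, 2, 4], 2), [1])

    def test_constant_vector_all_zero(self):
        for d in (1, 2, 3):
            assert np.all(cp.diff_operator(np.full(10, 0.7), d) == 0)

    def test_d_too_large_raises(self):
        with pytest.raises(ValueError):
            cp.diff_operator([1.0, 2.0], 2)

    def test_penalty_zero_at_zero(self):
        w = cp.WeightMatrix.zeros(3)
        assert cp.penalty(w, cp.PenaltyConfig(1.0, 1.0, 1)) == 0.0

    def test_penalty_constant_column(self):
        w = cp.WeightMatrix(np.full((cp.N_POSITIONS, 1), 0.2))
        val = cp.penalty(w, cp.PenaltyConfig(1.0, 1.0, 1))
        assert val == pytest.approx(149 * 0.2)

    def test_linear_ramp_vanishes_under_d2(self):
        ramp = np.linspace(0, 0.5, cp.N_POSITIONS)[:, None]
        w = cp.WeightMatrix(ramp)
        val = cp.penalty(w, cp.PenaltyConfig(0.0, 1.0, 2))
        assert val == pytest.approx(0.0, abs=1e-12)


class TestJaccard:
    def test_identity(self, small_dataset):
        assert cp.jaccard_exact(small_dataset.y, small_dataset.y, 0.2) == 1.0

    def test_set_arithmetic_third(self, make_pair):
        y, yhat = make_pair({1: row(A=0.5, C=0.5)}, {1: row(A=0.5, G=0.5)})
        assert cp.jaccard_exact(y, yhat, 0.2) == pytest.approx(1 / 3)

    def test_empty_sets_count_as_agreement(self, make_pair):
        y, yhat = make_pair({1: np.full(cp.N_AA, 0.05)},
                            {1: np.full(cp.N_AA, 0.05)})
        assert cp.jaccard_exact(y, yhat, 0.2) == 1.0

    def test_bounds(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(0)
        for _ in range(5):
            raw = rng.random((cp.N_POSITIONS, ds.xstar.p))
            raw /= raw.sum(axis=1, keepdims=True) + 0.5
            yhat = cp.predict(ds.x, ds.xstar, cp.WeightMatrix(raw))
            j = cp.jaccard_exact(ds.y, yhat, 0.2)
            assert 0.0 <= j <= 1.0

    def test_sigmoid_midpoint(self):
        cfg = cp.JaccardConfig(t=0.2, epsilon=7.0)
        assert M.smooth_membership(0.2, cfg) == pytest.approx(0.5)

    def test_smooth_converges_to_exact(self, small_dataset):
        """With frequencies bounded away from t by delta and eps = 50/delta,
        the surrogate matches the exact metric to 1e-6."""
        ds = small_dataset
        rng = np.random.default_rng(5)
        delta = 0.05
        for _ in range(5):
            # random rows pushed off the cutoff band [t-delta, t+delta]
            raw = rng.dirichlet(np.full(cp.N_AA, 0.3),
                                size=(len(ds.y), cp.N_POSITIONS))
            raw = np.where(np.abs(raw - 0.2) < delta,
                           np.where(raw < 0.2, 0.2 - delta, 0.2 + delta), raw)
            yhat = cp.ProfileTensor(
                np.where(ds.y.defined[:, :, None], raw, 0.0),
                ds.y.defined.copy(), ds.y.cf_ids)
            exact = cp.jaccard_exact(ds.y, yhat, 0.2)
            smooth = cp.jaccard_smooth(ds.y, yhat,
                                       cp.JaccardConfig(0.2, 50 / delta))
            assert abs(smooth - exact) < 1e-6


class TestFit:
    def test_huge_lasso_drives_alpha_to_zero(self, exact_dataset):
        ds = exact_dataset
        res = cp.fit("l2", ds.x, ds.xstar, ds.y,
                     cp.PenaltyConfig(lambda1=1e6))
        assert np.all(np.abs(res.weights.alpha) <= 1e-4)

    def test_matches_exhaustive_grid_search(self):
        """Tiny instance (2 CFs, 3 active positions, p=1): per-position
        1D grid search at step 0.001 is the oracle."""
        rng = np.random.default_rng(21)
        positions = (10, 11, 12)
        n, p = 2, 1
        xf = np.zeros((n, cp.N_POSITIONS, cp.N_AA))
        yf = np.zeros((n, cp.N_POSITIONS, cp.N_AA))
        vals = np.zeros((n, cp.N_POSITIONS, cp.N_AA, p))
        defined = np.zeros((n, cp.N_POSITIONS), dtype=bool)
        for i in range(n):
            for j in positions:
                xf[i, j - 1] = rng.dirichlet(np.ones(cp.N_AA))
                yf[i, j - 1] = rng.dirichlet(np.ones(cp.N_AA))
                vals[i, j - 1, :, 0] = rng.dirichlet(np.ones(cp.N_AA))
                defined[i, j - 1] = True
        x = cp.ProfileTensor(xf, defined.copy(), ("a", "b"))
        y = cp.ProfileTensor(yf, defined.copy(), ("a", "b"))
        xstar = InputTensor(vals, (ProfileSourceSpec("custom", label="s"),),
                            defined.copy())
        res = cp.fit("l2", x, xstar, y)
        grid = np.arange(0, 1.0005, 0.001)
        for j in positions:
            # brute-force the per-position quadratic objective
            best, best_val = None, np.inf
            for a in grid:
                pred = a * vals[:, j - 1, :, 0] + (1 - a) * xf[:, j - 1]
                val = ((yf[:, j - 1] - pred) ** 2).sum()
                if val < best_val:
                    best, best_val = a, val
            assert res.weights.alpha[j - 1, 0] == pytest.approx(best, abs=5e-3)

    def test_exact_generative_recovery(self, exact_dataset):
        ds = exact_dataset
        res = cp.fit("l2", ds.x, ds.xstar, ds.y)
        active = ds.y.defined[0]
        err = np.abs(res.weights.alpha[active] -
                     ds.truth["alpha_true"][active]).max()
        assert err < 1e-3

    def test_objective_never_worse_than_init(self, small_dataset):
        ds = small_dataset
        pcfg = cp.PenaltyConfig(1e-4, 1e-4, 1)
        res = cp.fit("l2", ds.x, ds.xstar, ds.y, pcfg)
        init_val = M.penalized_objective("l2", ds.x, ds.xstar, ds.y,
                                         cp.WeightMatrix.zeros(ds.xstar.p),
                                         pcfg)
        assert res.objective_value <= init_val + 1e-12

    def test_jaccard_smooth_fit_improves_similarity(self, exact_dataset):
        ds = exact_dataset
        jcfg = cp.JaccardConfig(t=0.2, epsilon=30.0)
        res = cp.fit("jaccard_smooth", ds.x, ds.xstar, ds.y, jcfg=jcfg,
                     opts=cp.FitOptions(maxiter=300))
        base = cp.jaccard_exact(ds.y, cp.predict(
            ds.x, ds.xstar, cp.WeightMatrix.zeros(ds.xstar.p)), 0.2)
        fitted = cp.jaccard_exact(ds.y, cp.predict(ds.x, ds.xstar,
                                                   res.weights), 0.2)
        assert fitted >= base

    def test_convexity_of_penalized_l2(self, small_dataset):
        """Midpoint convexity on random feasible pairs."""
        ds = small_dataset
        pcfg = cp.PenaltyConfig(1e-5, 1e-5, 1)
        rng = np.random.default_rng(8)
        for _ in range(10):
            a1 = rng.random((cp.N_POSITIONS, ds.xstar.p))
            a2 = rng.random((cp.N_POSITIONS, ds.xstar.p))
            a1 /= np.maximum(a1.sum(axis=1, keepdims=True), 1.0) + 1e-9
            a2 /= np.maximum(a2.sum(axis=1, keepdims=True), 1.0) + 1e-9
            f = lambda a: M.penalized_objective(
                "l2", ds.x, ds.xstar, ds.y, cp.WeightMatrix(a), pcfg)
            mid = f((a1 + a2) / 2)
            assert mid <= 0.5 * f(a1) + 0.5 * f(a2) + 1e-9

    def test_lambda1_monotone_shrinks_l1_norm(self, small_dataset):
        ds = small_dataset
        norms = []
        for lam in (0.0, 1e-4, 1e-3, 1e-2):
            res = cp.fit("l2", ds.x, ds.xstar, ds.y,
                         cp.PenaltyConfig(lambda1=lam))
            norms.append(np.abs(res.weights.alpha).sum())
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_lambda2_monotone_shrinks_roughness(self, small_dataset):
        ds = small_dataset
        rough = []
        for lam in (0.0, 1e-4, 1e-3, 1e-2):
            res = cp.fit("l2", ds.x, ds.xstar, ds.y,
                         cp.PenaltyConfig(lambda2=lam, d=1))
            r = sum(np.abs(np.diff(res.weights.alpha[:, l])).sum()
                    for l in range(ds.xstar.p))
            rough.append(r)
        assert all(a >= b - 1e-6 for a, b in zip(rough, rough[1:]))

    def test_projection_respects_constraints(self):
        rng = np.random.default_rng(2)
        raw = rng.random((cp.N_POSITIONS, 4)) * 2 - 0.5
        proj = M.project_feasible(raw)
        assert np.all(proj >= 0) and np.all(proj <= 1)
        assert np.all(proj.sum(axis=1) <= 1 + 1e-9)
        # already-feasible points are untouched
        feas = rng.random((cp.N_POSITIONS, 4)) / 8
        np.testing.assert_allclose(M.project_feasible(feas), feas)
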