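import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from dsmap.grid_symmetry import pack_voxels
from dsmap.scaling import (
    LeastSquaresProblem,
    ParamGrid,
    RefinementConfig,
    ScalingModel,
    assemble_problem,
    fit_parameter,
    interp_operator,
    laplacian_operator,
    merge_scaled,
    refine,
    renormalize_alpha,
    restrain_offset,
    second_derivative_operator,
)


class TestInterpOperator:
    def test_unit_row_at_control_point(self):
        M = interp_operator([2.0], [np.array([0.0, 1.0, 2.0, 3.0])])
        np.testing.assert_allclose(M.toarray(), [[0, 0, 1, 0]])

    def test_1d_midpoint(self):
        M = interp_operator([0.5], [np.array([0.0, 1.0])])
        np.testing.assert_allclose(M.toarray(), [[0.5, 0.5]])

    def test_3d_cell_center_has_eight_equal_weights(self):
        axes = [np.array([0.0, 1.0])] * 3
        M = interp_operator([[0.5, 0.5, 0.5]], axes)
        np.testing.assert_allclose(np.sort(M.toarray().ravel()), 0.125)

    def test_rows_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(0)
        axes = [np.linspace(0, 10, 7), np.linspace(-3, 3, 5)]
        pts = rng.uniform(-5, 15, size=(300, 2))  # includes out-of-range
        M = interp_operator(pts, axes)
        np.testing.assert_allclose(np.asarray(M.sum(axis=1)).ravel(), 1.0, rtol=1e-12)
        assert (M.data >= 0).all()

    def test_interpolates_linear_functions_exactly(self):
        axes = [np.linspace(0, 1, 6), np.linspace(0, 2, 4)]
        X, Y = np.meshgrid(*axes, indexing="ij")
        values = (3 * X - Y + 1).ravel()
        rng = np.random.default_rng(1)
        pts = rng.uniform([0, 0], [1, 2], size=(100, 2))
        got = interp_operator(pts, axes) @ values
        np.testing.assert_allclose(got, 3 * pts[:, 0] - pts[:, 1] + 1, rtol=1e-12)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            interp_operator([0.0], [np.array([])])


class TestRegularizerOperators:
    def test_second_derivative_annihilates_affine(self):
        D = second_derivative_operator(8)
        assert D.shape == (6, 8)
        x = 3.0 * np.arange(8) - 2.0
        np.testing.assert_allclose(D @ x, 0.0, atol=1e-12)
        np.testing.assert_allclose(D @ np.arange(8.0) ** 2, 2.0)

    def test_second_derivative_degenerate_sizes(self):
        assert second_derivative_operator(2).shape == (0, 2)

    def test_laplacian_annihilates_planes(self):
        L = laplacian_operator(5, 6)
        X, Y = np.meshgrid(np.arange(5.0), np.arange(6.0), indexing="ij")
        plane = (2 * X - 3 * Y + 1).ravel()
        np.testing.assert_allclose(L @ plane, 0.0, atol=1e-12)
        np.testing.assert_allclose(L @ (X**2 + Y**2).ravel(), 4.0)

    def test_laplacian_degenerate_sizes(self):
        assert laplacian_operator(2, 2).shape == (0, 4)


class TestAlphaRenormalization:
    def test_equal_operators_give_alpha(self):
        A = sparse.csr_matrix(np.array([[1.0, 2.0], [0.0, 3.0]]))
        assert renormalize_alpha(0.7, A, A) == pytest.approx(0.7)

    def test_quadratic_in_design_scale(self):
        A = sparse.random(20, 5, density=0.5, random_state=0, format="csr")
        B = sparse.identity(5, format="csr")
        assert renormalize_alpha(1.0, 2 * A, B) == pytest.approx(
            4 * renormalize_alpha(1.0, A, B)
        )

    def test_zero_alpha_or_empty_regularizer(self):
        A = sparse.identity(4, format="csr")
        assert renormalize_alpha(0.0, A, A) == 0.0
        assert renormalize_alpha(1.0, A, sparse.csr_matrix((0, 4))) == 0.0


class TestOffsetRestraint:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((-0.2, 0.5, 1.0), (0.0, 0.5, 1.0)),  # clip branch
            ((0.3, 0.5), (0.0, 0.2)),  # subtract-constant branch
            ((0.0, 0.7), (0.0, 0.7)),  # already touches zero
        ],
    )
    def test_restraint_branches(self, values, expected):
        np.testing.assert_allclose(restrain_offset(values), expected)

    def test_result_is_nonnegative_with_zero_minimum(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            out = restrain_offset(rng.normal(1.0, 2.0, size=30))
            assert out.min() == pytest.approx(0.0, abs=1e-15)
            assert (out >= 0).all()


class TestFitParameter:
    def test_identity_design_returns_target(self):
        A = sparse.identity(5, format="csr")
        b = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        x = fit_parameter(LeastSquaresProblem(A, b))
        np.testing.assert_allclose(x, b, rtol=1e-12)

    def test_noiseless_recovery_is_exact(self):
        """Forward-simulate from a known smooth b(phi) and solve: the
        unregularized solution reproduces the control points exactly."""
        axes = [np.linspace(0, 50, 21)]
        truth = 1.0 + 0.3 * np.sin(axes[0] / 8.0)
        rng = np.random.default_rng(3)
        phi = rng.uniform(0, 50, 500)
        M = interp_operator(phi, axes)
        b = M @ truth
        x = fit_parameter(LeastSquaresProblem(M.tocsr(), b))
        np.testing.assert_allclose(x, truth, rtol=1e-10)

    def test_strong_smoothing_approaches_affine_fit(self):
        axes = [np.linspace(0, 10, 15)]
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 10, 400)
        M = interp_operator(t, axes)
        y = 2.0 + 0.5 * t + rng.normal(0, 0.3, len(t))
        D = second_derivative_operator(15)
        x = fit_parameter(LeastSquaresProblem(M.tocsr(), y, [("smooth", D, 1e6)]))
        coeffs = np.polyfit(axes[0], x, 1)
        resid = x - np.polyval(coeffs, axes[0])
        assert np.abs(resid).max() < 1e-3 * np.abs(x).max()

    def test_underdetermined_without_regularization_raises(self):
        M = interp_operator([0.1], [np.linspace(0, 1, 10)])
        with pytest.raises(ValueError, match="alpha"):
            fit_parameter(LeastSquaresProblem(M.tocsr(), np.array([1.0])))


class TestMerging:
    def make_obs(self, rows):
        df = pd.DataFrame(rows, columns=["asu_key", "I", "sigma"])
        df["s"] = 0.1
        return df

    def test_single_observation_is_identity(self):
        merged = merge_scaled(self.make_obs([[5, 2.5, 0.5]]))
        assert merged.I.iloc[0] == pytest.approx(2.5)
        assert merged.sigma.iloc[0] == pytest.approx(0.5)

    def test_equal_sigmas_average(self):
        merged = merge_scaled(self.make_obs([[5, 1.0, 0.3], [5, 3.0, 0.3]]))
        assert merged.I.iloc[0] == pytest.approx(2.0)
        assert merged.sigma.iloc[0] == pytest.approx(0.3 / np.sqrt(2))

    def test_inverse_variance_weighting(self):
        merged = merge_scaled(self.make_obs([[5, 1.0, 1.0], [5, 3.0, 2.0]]))
        assert merged.I.iloc[0] == pytest.approx(1.4)
        assert merged.sigma.iloc[0] == pytest.approx(0.8944, abs=1e-4)

    def test_zero_sigma_observations_excluded(self):
        merged = merge_scaled(self.make_obs([[5, 9.0, 0.0], [6, 1.0, 1.0]]))
        assert list(merged.asu_key) == [6]

    def test_matches_brute_force_orbit_oracle(self, small_experiment):
        """Vectorized merge equals the closed-form inverse-variance mean
        computed voxel by voxel in a Python loop."""
        _, obs, _ = small_experiment
        sub = obs.iloc[:4000]
        merged = merge_scaled(sub).set_index("asu_key")
        rng = np.random.default_rng(5)
        keys = rng.choice(sub.asu_key.unique(), size=50, replace=False)
        for key in keys:
            grp = sub[(sub.asu_key == key) & (sub.sigma > 0)]
            w = 1.0 / grp.sigma**2
            i0 = float((w * grp.I).sum() / w.sum())
            s0 = float(1.0 / np.sqrt(w.sum()))
            assert merged.loc[key, "I"] == pytest.approx(i0, rel=1e-12)
            assert merged.loc[key, "sigma"] == pytest.approx(s0, rel=1e-12)


class TestAssembleProblem:
    def setup_method(self):
        self.axes = [np.linspace(0, 50, 11)]
        self.M = interp_operator(np.linspace(0, 50, 40), self.axes)
        n = 40
        rng = np.random.default_rng(6)
        self.I = rng.uniform(5, 10, n)
        self.sigma = rng.uniform(0.5, 1.0, n)
        self.i0 = rng.uniform(4, 9, n)
        self.ones = np.ones(n)
        self.zeros = np.zeros(n)

    def partners(self, **kw):
        base = {"a": self.ones, "b": self.ones, "c": self.zeros, "d": self.ones}
        base.update(kw)
        return base

    def test_b_problem_reduces_to_plain_scaling(self):
        prob = assemble_problem(
            "b", self.I, self.sigma, self.i0, self.partners(), self.M, [],
            {"smooth": 1.0, "magnitude": 1.0},
        )
        expected_A = sparse.diags(self.i0 / self.sigma) @ self.M
        np.testing.assert_allclose(prob.A.toarray(), expected_A.toarray())
        np.testing.assert_allclose(prob.b, self.I / self.sigma)

    def test_c_problem_with_unit_partners(self):
        prob = assemble_problem(
            "c", self.I, self.sigma, self.i0, self.partners(), self.M, [],
            {"smooth": 1.0, "magnitude": 1.0},
        )
        np.testing.assert_allclose(
            prob.A.toarray(), (sparse.diags(1 / self.sigma) @ self.M).toarray()
        )
        np.testing.assert_allclose(prob.b, (self.I - self.i0) / self.sigma)

    @pytest.mark.parametrize("kind", ["a", "b", "c", "d"])
    def test_noiseless_fixture_has_zero_residual(self, kind):
        """For data generated exactly by the model, the true parameter
        vector satisfies A x = b for every parameter's problem."""
        x_true = np.linspace(0.8, 1.2, 11) if kind != "c" else np.linspace(0, 0.5, 11)
        vals = self.M @ x_true
        partners = self.partners()
        if kind == "c":
            o = vals
            m = np.ones_like(vals)
        else:
            partners = self.partners(**{kind: vals})
            m = vals
            o = np.zeros_like(vals)
        I = m * self.i0 + o
        prob = assemble_problem(
            kind, I, self.sigma, self.i0, partners, self.M, [],
            {"smooth": 1.0, "magnitude": 1.0},
        )
        np.testing.assert_allclose(prob.A @ x_true, prob.b, atol=1e-12)


def _flat_obs(n_vox=60, n_rep=6, seed=0):
    """Observations with no artifacts: every voxel measured n_rep times."""
    rng = np.random.default_rng(seed)
    keys = np.repeat(np.arange(n_vox) + 100, n_rep)
    i0 = np.repeat(rng.uniform(5, 15, n_vox), n_rep)
    sigma = np.full(len(keys), 0.5)
    return pd.DataFrame(
        {
            "batch": 0,
            "phi": rng.uniform(0, 50, len(keys)),
            "x": rng.uniform(0, 100, len(keys)),
            "y": rng.uniform(0, 100, len(keys)),
            "s": np.repeat(rng.uniform(0.1, 0.6, n_vox), n_rep),
            "I": i0 + rng.normal(0, 0.5, len(keys)),
            "sigma": sigma,
            "asu_key": keys,
        }
    )


class TestRefinement:
    def test_flat_data_yields_identity_model(self):
        obs = _flat_obs()
        model, merged, diag = refine(obs, RefinementConfig())
        for grid in model.params["b"].values():
            np.testing.assert_allclose(grid.values, 1.0, atol=0.05)
        raw = merge_scaled(obs)
        joined = merged.merge(raw, on="asu_key", suffixes=("_m", "_r"))
        np.testing.assert_allclose(joined.I_m, joined.I_r, rtol=0.05)

    def test_two_sweeps_differing_by_factor_two(self):
        """Second sweep twice as bright: fitted b ratio is 2:1 after gauge
        fixing (mean b = 1)."""
        obs1 = _flat_obs(seed=1)
        obs2 = obs1.copy()
        obs2["batch"] = 1
        obs2["I"] = obs1.I * 2
        obs2["sigma"] = obs1.sigma * 2
        both = pd.concat([obs1, obs2], ignore_index=True)
        model, _, _ = refine(both, RefinementConfig())
        b0 = model.params["b"][0].values.mean()
        b1 = model.params["b"][1].values.mean()
        assert b1 / b0 == pytest.approx(2.0, rel=0.02)
        assert np.concatenate(
            [g.values.ravel() for g in model.params["b"].values()]
        ).mean() == pytest.approx(1.0, rel=1e-9)

    def test_gauge_invariance_of_predictions(self, small_experiment):
        """Scaling all intensities by k changes b and I0 but not the
        predicted intensities after gauge fixing."""
        _, obs, _ = small_experiment
        cfg = RefinementConfig()
        m1, merged1, d1 = refine(obs, cfg)
        scaled = obs.assign(I=obs.I * 3.0, sigma=obs.sigma * 3.0)
        m2, merged2, d2 = refine(scaled, cfg)
        j = merged1.merge(merged2, on="asu_key", suffixes=("_1", "_2"))
        np.testing.assert_allclose(j.I_2, 3.0 * j.I_1, rtol=1e-6)
        np.testing.assert_allclose(d1["m"], d2["m"], rtol=1e-6)

    def test_chi2_is_nonincreasing_without_restraints(self, small_experiment):
        """b-only refinement (no positivity restraint active) has a
        monotonically non-increasing chi2 trajectory."""
        _, obs, _ = small_experiment
        _, _, diag = refine(obs, RefinementConfig(outlier_sigma=1e9))
        chi2 = np.asarray(diag["chi2_per_obs"])
        assert np.all(np.diff(chi2) <= 1e-9 * chi2[:-1])

    def test_vacuous_scaling_rejected(self):
        obs = _flat_obs(n_vox=10, n_rep=1)
        with pytest.raises(ValueError, match="vacuous"):
            refine(obs, RefinementConfig())

    def test_offset_values_respect_positivity(self, small_experiment):
        _, obs, _ = small_experiment
        cfg = RefinementConfig(enable_c=True)
        model, _, _ = refine(obs, cfg)
        for grid in model.params["c"].values():
            assert grid.values.min() >= 0.0
            assert grid.values.min() == pytest.approx(0.0, abs=1e-12)
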