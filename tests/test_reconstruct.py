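"""Regression assembly, the constrained solve and the error metric."""

import warnings

import numpy as np
import pytest

import phagenet as pn
from phagenet.exceptions import ConditioningWarning, DimensionError


def analytic_system(truth, m, H, ones_ok=True):
    """Regression system whose W holds exact log-derivatives for given hosts."""
    H_aug = np.vstack([H, np.ones(H.shape[1])])
    W = truth.T @ H - m[:, None]
    return pn.RegressionSystem(W=W, H_aug=H_aug)


class TestBuildRegression:
    def test_dimension_bookkeeping_96h_6min(self, trajectory):
        sys = pn.build_regression(trajectory)
        assert sys.W.shape == (10, 960)
        assert sys.H_aug.shape == (11, 960)
        assert (sys.H_aug[-1] == 1).all()

    def test_constant_virus_series_gives_zero_w(self):
        ts = pn.CommunityTimeSeries(
            times=np.arange(5) * 0.1,
            H=np.vstack([np.linspace(1e3, 2e3, 5)]),
            V=np.full((2, 5), 1e6),
        )
        assert (pn.build_regression(ts).W == 0).all()

    def test_exponential_decay_gives_exact_rate(self):
        t = np.arange(20) * 0.25
        ts = pn.CommunityTimeSeries(
            times=t, H=np.full((1, 20), 1e3), V=np.vstack([1e6 * np.exp(-0.3 * t)])
        )
        np.testing.assert_allclose(pn.build_regression(ts).W, -0.3, rtol=1e-12)

    def test_hosts_taken_at_left_endpoint(self):
        ts = pn.CommunityTimeSeries(
            times=[0.0, 0.1, 0.2],
            H=np.array([[1.0, 2.0, 3.0]]),
            V=np.array([[1.0, 2.0, 4.0]]),
        )
        np.testing.assert_array_equal(pn.build_regression(ts).H_aug[0], [1.0, 2.0])
        np.testing.assert_array_equal(
            pn.build_regression(ts, midpoint=True).H_aug[0], [1.5, 2.5]
        )

    def test_rejects_nonpositive_densities_and_short_series(self):
        with pytest.raises(ValueError):
            pn.build_regression(
                pn.CommunityTimeSeries(times=[0.0], H=[[1.0]], V=[[1.0]])
            )
        ts = pn.CommunityTimeSeries(times=[0.0, 0.1], H=[[1.0, 1.0]], V=[[1.0, 1.0]])
        ts.V = np.array([[1.0, 0.0]])  # corrupt after construction
        with pytest.raises(ValueError):
            pn.build_regression(ts)


class TestConcatExperiments:
    def test_single_system_is_identity(self, trajectory):
        sys = pn.build_regression(trajectory)
        out = pn.concat_experiments([sys])
        np.testing.assert_array_equal(out.W, sys.W)
        np.testing.assert_array_equal(out.H_aug, sys.H_aug)

    def test_twenty_blocks_of_48_make_960(self, trajectory):
        block = pn.build_regression(trajectory).first_columns(48)
        pooled = pn.concat_experiments([block] * 20)
        assert pooled.n_cols == 960
        assert (pooled.H_aug[-1] == 1).all()

    def test_column_order_does_not_change_the_optimum(self, community, trajectory):
        M, params, truth = community
        init = pn.perturbed_initial_state(params.H_star, params.V_star, 0.5, seed=77)
        ts2 = pn.integrate_and_sample(params, M, init, 6 / 1440, 0.2)
        a = pn.build_regression(trajectory).first_columns(48)
        b = pn.build_regression(ts2)
        r1 = pn.solve_network(pn.concat_experiments([a, b]))
        r2 = pn.solve_network(pn.concat_experiments([b, a]))
        assert r1.objective == pytest.approx(r2.objective, rel=1e-8, abs=1e-12)
        # solutions may differ at noise level in near-flat directions; 1e-9 is
        # two orders below the smallest physical rate (1e-7)
        np.testing.assert_allclose(
            r1.M_tilde.entries, r2.M_tilde.entries, rtol=1e-4, atol=1e-9
        )

    def test_shape_mismatch_rejected(self):
        s1 = pn.RegressionSystem(np.zeros((2, 3)), np.vstack([np.ones((1, 3)), np.ones(3)]))
        s2 = pn.RegressionSystem(np.zeros((3, 3)), np.vstack([np.ones((1, 3)), np.ones(3)]))
        with pytest.raises(DimensionError):
            pn.concat_experiments([s1, s2])


class TestSolveNetwork:
    def test_exact_log_derivatives_recover_truth(self, community, trajectory):
        M, params, truth = community
        sys = analytic_system(truth.entries, params.m, trajectory.H[:, :-1])
        res = pn.solve_network(sys)
        np.testing.assert_allclose(res.M_tilde.entries, truth.entries, rtol=1e-6, atol=1e-14)
        np.testing.assert_allclose(res.m, params.m, rtol=1e-6)
        assert res.error(truth) < 1e-6

    def test_zero_w_gives_zero_solution(self, rng):
        H = rng.uniform(1e3, 1e4, size=(4, 50))
        sys = pn.RegressionSystem(np.zeros((3, 50)), np.vstack([H, np.ones(50)]))
        res = pn.solve_network(sys)
        assert (res.M_tilde.entries == 0).all() and (res.m == 0).all()
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_per_row_solution_matches_joint_convex_solve(self, rng):
        # separability: stacking per-virus NNLS solutions equals the joint
        # bound-constrained least-squares optimum
        n_h, n_v, n_cols = 3, 2, 12
        truth = np.abs(rng.normal(1, 0.5, (n_h, n_v)))
        m = np.abs(rng.normal(0.5, 0.1, n_v))
        H = rng.uniform(0.5, 2.0, (n_h, n_cols))
        sys = analytic_system(truth, m, H)
        W_noisy = sys.W + rng.normal(0, 0.05, sys.W.shape)
        sys = pn.RegressionSystem(W_noisy, sys.H_aug)
        res_rows = pn.NetworkReconstruction(sys).fit(method="nnls")
        res_joint = pn.NetworkReconstruction(sys).fit(method="lsq_linear")
        assert res_rows.objective == pytest.approx(res_joint.objective, rel=1e-8)
        np.testing.assert_allclose(
            res_rows.M_tilde.entries, res_joint.M_tilde.entries, atol=1e-7
        )

    def test_underdetermined_system_warns(self, rng):
        H = rng.uniform(1e3, 1e4, size=(4, 3))
        sys = pn.RegressionSystem(np.zeros((2, 3)), np.vstack([H, np.ones(3)]))
        with pytest.warns(ConditioningWarning):
            pn.solve_network(sys)

    def test_identical_host_columns_warn_of_conditioning(self):
        H = np.tile(np.array([[1e3], [2e3]]), (1, 40))
        sys = pn.RegressionSystem(np.zeros((1, 40)), np.vstack([H, np.ones(40)]))
        with pytest.warns(ConditioningWarning):
            pn.solve_network(sys)

    def test_summary_reports_key_diagnostics(self, trajectory):
        res = pn.NetworkReconstruction(trajectory).fit()
        text = res.summary()
        assert "objective" in text and "cond" in text and "viruses: 10" in text


class TestReconstructionError:
    def test_identity_zero_and_double(self, community):
        _, _, truth = community
        assert pn.reconstruction_error(truth, truth) == 0.0
        zero = pn.QuantitativeNetwork(np.zeros_like(truth.entries))
        assert pn.reconstruction_error(truth, zero) == pytest.approx(1.0)
        double = pn.QuantitativeNetwork(2 * truth.entries)
        assert pn.reconstruction_error(truth, double) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pn.reconstruction_error(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            pn.reconstruction_error(np.ones((2, 2)), np.ones((2, 3)))
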