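"""Least-squares estimation of the occlusion rate."""

import numpy as np
import pytest

from occlufit import (
    InsufficientDataError,
    LogisticParams,
    OcclusionSeries,
    fit_all_groups,
    fit_logistic,
    fit_report_frame,
    goodness_of_fit,
    sse_objective,
    trajectory_on_grid,
)


def series_from(params, noise=None, days=None, **kw):
    days = np.arange(1, 8, dtype=float) if days is None else np.asarray(days, float)
    means = trajectory_on_grid(params, days)
    if noise is not None:
        means = means + np.asarray(noise, float)
    return OcclusionSeries(
        paste=kw.get("paste", "toy"),
        condition=kw.get("condition", "without_saliva"),
        days=days,
        means=means,
        sds=kw.get("sds", np.full_like(days, 2.0)),
        n=kw.get("n", 7),
    )


class TestSseObjective:
    def test_zero_iff_interpolating(self):
        p = LogisticParams(r=0.6, K=100, x0=15)
        assert sse_objective(series_from(p), p) == 0.0

    def test_quadratic_in_residual_scale(self):
        p = LogisticParams(r=0.6, K=100, x0=15)
        e = np.array([1.0, -0.5, 0.8, -1.2, 0.3, 0.9, -0.4])
        f1 = sse_objective(series_from(p, noise=e), p)
        f2 = sse_objective(series_from(p, noise=2 * e), p)
        assert f2 == pytest.approx(4 * f1, rel=1e-12)

    def test_matches_hand_summation_on_toy_series(self):
        p = LogisticParams(r=0.5, K=100, x0=10)
        s = OcclusionSeries(
            paste="toy", condition="with_saliva",
            days=[1, 2, 3], means=[20.0, 30.0, 45.0], sds=[1.0, 2.0, 3.0], n=5,
        )
        pred = [float(trajectory_on_grid(p, [d])[0]) for d in (1, 2, 3)]
        by_hand = sum((m - x) ** 2 for m, x in zip([20.0, 30.0, 45.0], pred))
        assert sse_objective(s, p) == pytest.approx(by_hand, rel=1e-12)
        weighted_by_hand = sum(
            (5 / sd**2) * (m - x) ** 2
            for m, x, sd in zip([20.0, 30.0, 45.0], pred, [1.0, 2.0, 3.0])
        )
        assert sse_objective(s, p, weights="inverse_variance") == pytest.approx(
            weighted_by_hand, rel=1e-12
        )

    def test_inverse_variance_rejects_zero_sd(self):
        p = LogisticParams(r=0.5, K=100, x0=10)
        s = series_from(p, sds=np.array([2, 2, 0, 2, 2, 2, 2.0]))
        with pytest.raises(ValueError, match="unweighted"):
            sse_objective(s, p, weights="inverse_variance")


class TestFitLogistic:
    def test_noiseless_joint_recovery(self):
        truth = LogisticParams(r=0.6, K=100, x0=15)
        res = fit_logistic(series_from(truth), x0_policy="fitted")
        assert res.converged
        assert res.params.r == pytest.approx(0.6, abs=1e-4)
        assert res.params.x0 == pytest.approx(15.0, abs=1e-3)
        assert res.sse <= 1e-10

    def test_dominates_grid_search(self, table1):
        """Optimizer SSE never exceeds the best of a dense (r, x0) grid."""
        s = table1[0]
        res = fit_logistic(s, x0_policy="fitted")
        rs = np.linspace(1e-6, 10, 60)
        x0s = np.linspace(1e-6, 100 - 1e-6, 60)
        grid_best = min(
            sse_objective(s, LogisticParams(r=r, K=100, x0=x0))
            for r in rs
            for x0 in x0s
        )
        assert res.sse <= grid_best + 1e-9

    def test_rescaling_K_and_data_leaves_rate_invariant(self):
        truth = LogisticParams(r=0.6, K=100, x0=15)
        base = series_from(truth, noise=[0.5, -0.4, 0.3, 0.2, -0.6, 0.1, -0.2])
        res100 = fit_logistic(base, K=100, x0_policy="fitted")
        c = 0.5
        scaled = OcclusionSeries(
            paste="toy", condition="without_saliva", days=base.days,
            means=base.means * c, sds=base.sds * c, n=base.n,
        )
        res50 = fit_logistic(scaled, K=100 * c, x0_policy="fitted")
        assert res50.params.r == pytest.approx(res100.params.r, abs=1e-5)
        assert res50.params.x0 == pytest.approx(res100.params.x0 * c, abs=1e-3)

    def test_monotone_data_yields_positive_rate(self):
        s = OcclusionSeries(
            paste="toy", condition="with_saliva",
            days=np.arange(1, 8),
            means=[12, 19, 33, 47, 62, 75, 84.0],
            sds=np.full(7, 2.0), n=7,
        )
        res = fit_logistic(s, x0_policy="fitted")
        assert res.params.r > 0

    def test_multistart_runs_agree_on_fixture(self, table1):
        """All converged starts land on the same rate for the study series."""
        for s in table1:
            res = fit_logistic(s, x0_policy="anchored", refine_all=True)
            assert res.multistart_r_spread is not None
            assert res.multistart_r_spread <= 1e-3

    def test_anchored_back_projects_first_mean(self, table1):
        s = table1[0]
        res = fit_logistic(s, x0_policy="anchored")
        # the fitted curve passes through the first observed (day, mean)
        first = trajectory_on_grid(res.params, [s.days[0]])[0]
        assert first == pytest.approx(s.means[0], abs=1e-9)

    def test_fixed_x0_policy(self):
        truth = LogisticParams(r=0.6, K=100, x0=15)
        res = fit_logistic(series_from(truth), x0_policy=15.0)
        assert res.params.x0 == 15.0
        assert res.params.r == pytest.approx(0.6, abs=1e-6)
        assert res.x0_policy.startswith("fixed_at_")

    def test_insufficient_data(self):
        truth = LogisticParams(r=0.6, K=100, x0=15)
        with pytest.raises(InsufficientDataError):
            fit_logistic(series_from(truth, days=[1, 2]))

    def test_low_carrying_capacity_warns(self):
        truth = LogisticParams(r=0.6, K=100, x0=15)
        with pytest.warns(UserWarning, match="cannot reach"):
            fit_logistic(series_from(truth), K=50.0, x0_policy="fitted")


class TestFitAllGroups:
    def test_saliva_orderings_under_replication_policy(self, table1):
        results = fit_all_groups(table1, x0_policy="anchored")
        r = {
            (s.paste, s.condition): res.params.r
            for s, res in zip(table1, results)
        }
        assert r[("EB@TiO2", "with_saliva")] > r[("EB@TiO2", "without_saliva")]
        assert (
            r[("Colgate Pro-relief", "without_saliva")]
            > r[("Colgate Pro-relief", "with_saliva")]
        )
        assert (
            r[("Sensodyne repair", "with_saliva")]
            > r[("Sensodyne repair", "without_saliva")]
        )

    def test_failures_flagged_not_fatal(self, table1):
        bad = OcclusionSeries(
            paste="degenerate", condition="with_saliva",
            days=np.arange(1, 8), means=np.zeros(7), sds=np.full(7, 1.0), n=7,
        )
        results = fit_all_groups([table1[0], bad], x0_policy="anchored")
        assert results[0].converged
        assert not results[1].converged
        assert results[1].error

    def test_report_frame_shape(self, table1):
        results = fit_all_groups(table1, x0_policy="anchored")
        frame = fit_report_frame(table1, results)
        assert len(frame) == 6
        assert set(frame["paste"]) == {
            "EB@TiO2", "Colgate Pro-relief", "Sensodyne repair"
        }
        assert frame["converged"].all()


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        p = LogisticParams(r=0.6, K=100, x0=15)
        rmse, r2 = goodness_of_fit(series_from(p), p)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_prediction_scores_zero(self):
        s = OcclusionSeries(
            paste="toy", condition="with_saliva",
            days=[1, 2, 3, 4], means=[10, 20, 30, 40.0], sds=[1, 1, 1, 1.0], n=7,
        )
        # r = 0 keeps the trajectory at x0 = the series mean
        rmse, r2 = goodness_of_fit(s, LogisticParams(r=0.0, K=100, x0=25.0))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_r2_undefined(self):
        s = OcclusionSeries(
            paste="toy", condition="with_saliva",
            days=[1, 2, 3], means=[30, 30, 30.0], sds=[1, 1, 1.0], n=7,
        )
        _, r2 = goodness_of_fit(s, LogisticParams(r=0.0, K=100, x0=30.0))
        assert np.isnan(r2)

    def test_bioglass_paste_fits_worse_than_composite(self, table1_by_cell):
        """The non-sigmoid Sensodyne series is the poorly fitted cell."""
        from occlufit import fit_logistic

        eb = fit_logistic(table1_by_cell[("EB@TiO2", "without_saliva")],
                          x0_policy="anchored")
        sen = fit_logistic(table1_by_cell[("Sensodyne repair", "without_saliva")],
                           x0_policy="anchored")
        assert sen.r_squared < eb.r_squared
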