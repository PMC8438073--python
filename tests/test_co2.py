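import numpy as np
import pandas as pd
import pytest

from dendrocp import (
    DataError,
    GnesModelSpec,
    GroundTruth,
    SlopeCpSpec,
    changepoint_summary,
    compare_response_shapes,
    fit_gnes_model,
    fit_slope_changepoint,
    generate_gradient,
    simulate_gnes_series,
    simulate_lambda_bar,
)

QUICK_GIBBS = GnesModelSpec(seed=0, n_iter=1200, n_burn=400)


@pytest.fixture(scope="module")
def gnes_setup():
    g = generate_gradient(30, 8, 0.06, 1.19, seed=21)
    truth = GroundTruth()
    long, lam_true = simulate_gnes_series(g, truth, 25, seed=22)
    return g, truth, long, lam_true


class TestGnesModel:
    def test_noise_free_slope_recovery(self):
        """With GNES exactly linear in CO2, lambda concentrates on the slope."""
        years = np.arange(2000, 2020)
        co2 = 370 + 1.9 * (years - 2000)
        rows = []
        rng = np.random.default_rng(5)
        slopes = {}
        for k in range(8):
            lam = 0.01 + 0.005 * k
            slopes[f"t{k}"] = lam
            for y, c in zip(years, co2):
                rows.append(
                    {"tree_id": f"t{k}", "year": y,
                     "gnes": lam * (c - co2.mean()),
                     "co2": c, "may_tmin": 0.0}
                )
        long = pd.DataFrame(rows)
        coords = np.array([[k, 0.0] for k in range(8)], dtype=float)
        post = fit_gnes_model(long, coords, QUICK_GIBBS)
        for tid, lam in slopes.items():
            assert post.lambda_mean[tid] == pytest.approx(lam, abs=2e-4)

    def test_row_permutation_invariance(self, gnes_setup):
        """Rows are exchangeable: permuting year order (covariates moved
        identically) leaves the posterior unchanged up to Monte Carlo and
        float-summation-order noise."""
        g, truth, long, _ = gnes_setup
        post1 = fit_gnes_model(long, g, QUICK_GIBBS)
        shuffled = long.sample(frac=1.0, random_state=1)
        post2 = fit_gnes_model(shuffled, g, QUICK_GIBBS)
        assert np.allclose(
            post1.lambda_mean.to_numpy(), post2.lambda_mean.to_numpy(), atol=2e-3
        )

    def test_lambda_close_to_per_tree_least_squares(self, gnes_setup):
        g, truth, long, lam_true = gnes_setup
        post = fit_gnes_model(long, g, QUICK_GIBBS)
        co2_mean = long["co2"].mean()
        ols = {}
        for tid, grp in long.groupby("tree_id"):
            x = np.column_stack(
                [np.ones(len(grp)), grp["co2"] - co2_mean, grp["may_tmin"]]
            )
            beta, *_ = np.linalg.lstsq(x, grp["gnes"], rcond=None)
            ols[tid] = beta[1]
        ols = np.array([ols[t] for t in post.tree_ids])
        hat = post.lambda_mean.to_numpy()
        truth_v = lam_true.loc[post.tree_ids].to_numpy()
        rmse_hat = np.sqrt(np.mean((hat - truth_v) ** 2))
        rmse_ols = np.sqrt(np.mean((ols - truth_v) ** 2))
        assert rmse_hat <= 1.25 * rmse_ols + 1e-4
        assert np.corrcoef(hat, ols)[0, 1] > 0.99

    def test_co2_affine_rescaling(self, gnes_setup):
        """Slopes rescale exactly inversely when CO2 changes units."""
        g, truth, long, _ = gnes_setup
        post1 = fit_gnes_model(long, g, QUICK_GIBBS)
        scaled = long.copy()
        scaled["co2"] = scaled["co2"] * 10.0 + 300.0
        post2 = fit_gnes_model(scaled, g, QUICK_GIBBS)
        ratio = post1.lambda_mean / post2.lambda_mean
        assert np.allclose(ratio, 10.0, rtol=0.02)

    def test_constant_co2_rejected(self, gnes_setup):
        g, truth, long, _ = gnes_setup
        flat = long.copy()
        flat["co2"] = 400.0
        with pytest.raises(DataError, match="constant"):
            fit_gnes_model(flat, g)


class TestSlopeChangepoint:
    def test_recovery_covers_truth(self):
        g = generate_gradient(54, 12, 0.06, 1.19, seed=30)
        truth = GroundTruth()
        lam = simulate_lambda_bar(g, truth, seed=31)
        m = g.set_index("tree_id").loc[lam.index, "nminer"]
        post = fit_slope_changepoint(lam, m, SlopeCpSpec(seed=32))
        lo, hi = np.quantile(post.draws["cp"], [0.025, 0.975])
        assert lo <= truth.co2.change_point <= hi

    def test_no_break_truth_diffuse(self):
        g = generate_gradient(54, 12, 0.06, 1.19, seed=33)
        truth = GroundTruth()
        truth.co2.theta2 = 0.0
        truth.co2.theta4 = 0.0
        truth.co2.theta3 = -0.02
        lam = simulate_lambda_bar(g, truth, seed=34)
        m = g.set_index("tree_id").loc[lam.index, "nminer"]
        post = fit_slope_changepoint(lam, m, SlopeCpSpec(seed=35))
        cs = changepoint_summary(post)
        assert post.draws["cp"].std() > 0.2
        # the two segment slopes are compatible with each other
        assert not cs.slopes_differ

    def test_noiseless_two_segment_localizes_break(self):
        """Exact two-segment data: the break lands between the abutting
        mineralization values, as a grid least-squares oracle predicts."""
        m = np.concatenate([np.linspace(0.1, 0.4, 10), np.linspace(0.5, 1.1, 10)])
        # below segment ends at 0.04, above sits at 0: a clean step at the gap
        lam = np.where(m <= 0.45, 0.06 - 0.05 * m, 0.0)
        rng = np.random.default_rng(0)
        lam = lam + rng.normal(0, 1e-5, len(m))
        # grid least-squares oracle: SSE minimal only for cp inside (0.4, 0.5)
        grid = np.linspace(0.05, 1.2, 231)
        sses = []
        for cp in grid:
            j = (m > cp).astype(float)
            x = np.column_stack([np.ones_like(m), j, m, j * m])
            th, *_ = np.linalg.lstsq(x, lam, rcond=None)
            sses.append(np.sum((lam - x @ th) ** 2))
        best = grid[np.argmin(sses)]
        assert 0.4 < best < 0.5
        post = fit_slope_changepoint(lam, m, SlopeCpSpec(seed=3))
        inside = post.draws["cp"].between(0.4, 0.5).mean()
        assert inside > 0.95

    def test_too_few_trees(self):
        with pytest.raises(DataError, match=">= 8"):
            fit_slope_changepoint(np.zeros(5), np.linspace(0.1, 1, 5))

    def test_measurement_error_mode_runs(self):
        g = generate_gradient(20, 6, 0.06, 1.19, seed=36)
        truth = GroundTruth()
        lam = simulate_lambda_bar(g, truth, seed=37)
        m = g.set_index("tree_id").loc[lam.index, "nminer"]
        spec = SlopeCpSpec(seed=38, measurement_error=True,
                           n_cp_grid=101, n_var_grid=41, n_draws=500)
        post = fit_slope_changepoint(
            lam, m, spec, lambda_sd=np.full(len(m), 0.002)
        )
        assert len(post.draws) == 500


class TestShapeComparison:
    def test_deterministic(self):
        g = generate_gradient(30, 8, 0.06, 1.19, seed=40)
        lam = simulate_lambda_bar(g, GroundTruth(), seed=41)
        m = g.set_index("tree_id").loc[lam.index, "nminer"]
        a = compare_response_shapes(lam, m, SlopeCpSpec(seed=42))
        b = compare_response_shapes(lam, m, SlopeCpSpec(seed=42))
        pd.testing.assert_frame_equal(a.table, b.table)
        assert set(a.table["model"]) == {
            "changepoint", "linear", "logarithmic", "exp_decay"
        }

    def test_break_data_prefers_changepoint(self):
        g = generate_gradient(54, 12, 0.06, 1.19, seed=43)
        lam = simulate_lambda_bar(g, GroundTruth(), seed=44)
        m = g.set_index("tree_id").loc[lam.index, "nminer"]
        cmp_ = compare_response_shapes(lam, m, SlopeCpSpec(seed=45))
        assert cmp_.best == "changepoint"
        assert (cmp_.table["p_d"] > 0).all()


def test_pipeline_composes_end_to_end():
    """Full composition: GNES simulation -> per-tree slopes -> change-point.

    Checks the structural contract of the chain: one slope per tree carried
    into stage 2 with a complete summary. The statistical headline pattern
    (below-break slope excludes zero, above does not) is a replicate-level
    property and is asserted over 20 runs in the acceptance suite."""
    g = generate_gradient(30, 8, 0.06, 1.19, seed=50)
    truth = GroundTruth()
    long, _ = simulate_gnes_series(g, truth, 20, seed=51)
    s1 = fit_gnes_model(long, g, GnesModelSpec(seed=52, n_iter=800, n_burn=300))
    assert list(s1.lambda_table().index) == s1.tree_ids
    m = g.set_index("tree_id").loc[s1.tree_ids, "nminer"]
    s2 = fit_slope_changepoint(s1.lambda_mean, m, SlopeCpSpec(seed=53))
    cs = changepoint_summary(s2)
    assert 0.0 <= cs.cp_mean <= 1.25
    assert np.isfinite([*cs.slope_below_ci, *cs.slope_above_ci]).all()
    assert len(s2.draws) == SlopeCpSpec().n_draws
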