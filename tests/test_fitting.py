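import numpy as np
import pytest

from boldnvc import (PenaltyConfig, TimeSeries, compute_cost, make_model,
                     optimize, refit_for_condition, simulate, single_trial)
from boldnvc.fitting import SENTINEL_COST


def exact_data(model, params, paradigm, grid, sem=1.0):
    """Data equal to the model's own simulation (zero residual by design)."""
    sim = simulate(model, params, paradigm, grid)
    return TimeSeries(grid, sim.y, np.full(len(grid), sem), "exact")


@pytest.fixture(scope="module")
def fit_grid():
    return np.arange(0.0, 17.51, 0.5)


class TestComputeCost:
    def test_zero_for_perfect_match(self, mn2, mn2_truth, trial, fit_grid):
        data = exact_data(mn2, mn2_truth, trial, fit_grid)
        cost = compute_cost(mn2, mn2_truth, data, trial)
        assert cost == pytest.approx(0.0, abs=1e-8)

    def test_single_sigma_residual_costs_one(self, mn2, mn2_truth, trial,
                                             fit_grid):
        data = exact_data(mn2, mn2_truth, trial, fit_grid, sem=0.7)
        values = data.values.copy()
        values[10] += 0.7  # one residual equal to its SE
        bumped = TimeSeries(data.times, values, data.sem, "bumped")
        assert compute_cost(mn2, mn2_truth, bumped, trial) == pytest.approx(
            1.0, abs=1e-6)

    def test_reordering_data_points_is_irrelevant(self, mn2, mn2_truth, trial,
                                                  fit_grid):
        # the cost is a sum over points: evaluating on a sub-grid in two
        # halves gives the same total as the full grid
        data = exact_data(mn2, mn2_truth, trial, fit_grid, sem=0.5)
        values = data.values + 0.25
        full = TimeSeries(data.times, values, data.sem, "x")
        first = TimeSeries(data.times[:18], values[:18], data.sem[:18], "a")
        second = TimeSeries(data.times[17:], values[17:], data.sem[17:], "b")
        total = (compute_cost(mn2, mn2_truth, first, trial)
                 + compute_cost(mn2, mn2_truth, second, trial)
                 - ((values[17] - simulate(mn2, mn2_truth, trial,
                                           data.times).y[17]) / 0.5) ** 2)
        assert compute_cost(mn2, mn2_truth, full, trial) == pytest.approx(
            total, rel=1e-6)

    def test_missing_dip_penalty_formula(self, mn2, mn2_truth, trial,
                                         fit_grid, mm2):
        # perfect fit to dip-free data with require_dip on: shortfall equals
        # the threshold, so the penalty is exactly the weight
        from boldnvc import reference_parameter_set

        p = reference_parameter_set("Mm2_anaerobic")  # peak only, no dip
        data = exact_data(mm2, p, trial, fit_grid)
        pen = PenaltyConfig(require_dip=True, weight_dip=100.0,
                            dip_threshold=0.02 * data.values.max(),
                            peak_threshold=0.10 * data.values.max())
        cost = compute_cost(mm2, p, data, trial, penalties=pen)
        assert cost == pytest.approx(100.0, rel=1e-3)

    def test_penalty_zero_when_requirements_met(self, trial, fit_grid, mnm2):
        from boldnvc import reference_parameter_set

        p = reference_parameter_set("Mnm2_reference")
        data = exact_data(mnm2, p, trial, fit_grid)
        pen = PenaltyConfig(require_dip=True, require_undershoot=True,
                            dip_threshold=0.5, peak_threshold=2.5)
        assert compute_cost(mnm2, p, data, trial, penalties=pen) == \
            pytest.approx(0.0, abs=1e-8)

    def test_failed_simulation_returns_sentinel(self, mm2, trial, fit_grid):
        bad = {n: 1e3 for n in mm2.param_names}
        bad["v0"] = 1e-3
        data = TimeSeries(fit_grid, np.zeros(len(fit_grid)),
                          np.ones(len(fit_grid)), "x")
        cost = compute_cost(mm2, mm2.make_params(bad), data, trial)
        assert cost == SENTINEL_COST


class TestOptimize:
    def test_deterministic_for_fixed_seed(self, mn2, mn2_synthetic, trial):
        data = mn2_synthetic.window(0.0, 17.5)
        a = optimize(mn2, data, trial, seed=11, budget=300)
        b = optimize(mn2, data, trial, seed=11, budget=300)
        assert a.best_cost == b.best_cost
        np.testing.assert_array_equal(a.best_params.values, b.best_params.values)
        assert len(a.acceptable_archive) == len(b.acceptable_archive)

    def test_zero_budget_rejected(self, mn2, mn2_synthetic, trial):
        with pytest.raises(ValueError, match="budget"):
            optimize(mn2, mn2_synthetic.window(0, 17.5), trial,
                     seed=0, budget=0)

    def test_archive_members_satisfy_cutoff(self, mn2, mn2_synthetic, trial):
        data = mn2_synthetic.window(0.0, 17.5)
        fit = optimize(mn2, data, trial, seed=3, budget=2000)
        for values, cost in fit.acceptable_archive[:20]:
            assert cost <= fit.cutoff
            # re-evaluation reproduces the archived cost
            re_cost = compute_cost(mn2, values, data, trial,
                                   rtol=1e-6, atol=1e-8)
            assert re_cost == pytest.approx(cost, rel=1e-6, abs=1e-8)

    def test_noise_free_self_fit_reaches_tiny_cost(self, mn2, mn2_truth,
                                                   trial, fit_grid):
        # fitting the model to its own noise-free trace from a perturbed
        # warm start recovers an essentially exact fit
        data = exact_data(mn2, mn2_truth, trial, fit_grid, sem=1.0)
        start = mn2.make_params(
            {n: v * 1.3 for n, v in mn2_truth.as_dict().items()})
        fit = optimize(mn2, data, trial, seed=5, budget=15000,
                       x_start=start, n_restarts=1)
        assert fit.best_cost < 1e-3

    def test_json_and_tsv_serialization(self, mn2, mn2_synthetic, trial):
        import json

        fit = optimize(mn2, mn2_synthetic.window(0, 17.5), trial,
                       seed=1, budget=500)
        blob = json.loads(fit.to_json())
        assert blob["model"] == "Mn2"
        assert set(blob["best_params"]) == set(mn2.param_names)
        tsv = fit.archive_tsv()
        assert tsv.splitlines()[0].split("\t")[-1] == "cost"


class TestRefit:
    def test_warm_start_never_worse_on_same_data(self, mn2, mn2_synthetic,
                                                 trial):
        data = mn2_synthetic.window(0.0, 17.5)
        prior = optimize(mn2, data, trial, seed=2, budget=1500)
        refit = refit_for_condition(prior, mn2, data, trial, seed=9,
                                    budget=500)
        assert refit.best_cost <= prior.best_cost + 1e-9

    def test_model_mismatch_rejected(self, mn2, mm2, mn2_synthetic, trial):
        data = mn2_synthetic.window(0.0, 17.5)
        prior = optimize(mn2, data, trial, seed=2, budget=300)
        with pytest.raises(ValueError, match="prior fit"):
            refit_for_condition(prior, mm2, data, trial, seed=0, budget=300)

    def test_cutoff_recomputed_for_new_df(self, mn2, mn2_synthetic, trial):
        data = mn2_synthetic.window(0.0, 17.5)
        prior = optimize(mn2, data, trial, seed=2, budget=300)
        shorter = mn2_synthetic.window(0.0, 10.0)
        refit = refit_for_condition(prior, mn2, shorter, trial, seed=0,
                                    budget=300)
        from boldnvc import chi2_cutoff

        assert refit.cutoff == pytest.approx(
            chi2_cutoff(0.05, shorter.n_points - 1))
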