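import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gammaln

from boldnvc import (chi2_cutoff, chi2_test, evaluate_model,
                     glucose_plausibility, lr_test, make_model,
                     reference_parameter_set, simulate, single_trial,
                     verdict_table)
from boldnvc.evaluation import Verdict
from boldnvc.evaluation import TestOutcome as Outcome
from boldnvc.fitting import FitResult
from boldnvc.models import ParameterSet
from boldnvc.simulate import detect_features, dip_attribution


def chi2_quantile_by_quadrature(alpha, df):
    """Independent oracle: invert the chi-square CDF by direct quadrature of
    the density x^(df/2-1) e^(-x/2) / (2^(df/2) Gamma(df/2))."""
    lognorm = (df / 2) * np.log(2.0) + gammaln(df / 2)

    def pdf(x):
        return np.exp((df / 2 - 1) * np.log(x) - x / 2 - lognorm)

    def cdf(x):
        val, _ = quad(pdf, 0, x, limit=500)
        return val

    return brentq(lambda x: cdf(x) - (1 - alpha), 1e-9, 20 * df + 100,
                  xtol=1e-10)


class TestChi2Cutoff:
    def test_estimation_data_cutoff(self):
        # 36 time points -> df = 35
        assert chi2_cutoff(0.05, 35) == pytest.approx(49.8, abs=0.05)

    def test_lr_cutoff(self):
        assert chi2_cutoff(0.05, 22) == pytest.approx(33.9, abs=0.05)

    def test_cutoff_vanishes_as_alpha_approaches_one(self):
        assert chi2_cutoff(1 - 1e-6, 1) < 1e-6
        assert chi2_cutoff(0.5, 35) < chi2_cutoff(0.05, 35)

    @pytest.mark.parametrize("df", [1, 22, 35, 100])
    def test_agrees_with_quadrature_oracle(self, df):
        expected = chi2_quantile_by_quadrature(0.05, df)
        assert chi2_cutoff(0.05, df) == pytest.approx(expected, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_cutoff(0.0, 10)
        with pytest.raises(ValueError):
            chi2_cutoff(0.05, 0)


class TestChi2Test:
    def test_metabolic_fit_worked_example(self):
        # cost 45.5 on the 36-point estimation series is acceptable
        out = chi2_test(45.5, 36, alpha=0.05)
        assert out.passed
        assert out.df == 35
        assert out.cutoff == pytest.approx(49.8, abs=0.05)

    def test_zero_cost_passes(self):
        assert chi2_test(0.0, 36).passed

    def test_cost_above_cutoff_fails(self):
        assert not chi2_test(60.0, 36).passed

    def test_preconditions(self):
        with pytest.raises(ValueError):
            chi2_test(-1.0, 36)
        with pytest.raises(ValueError):
            chi2_test(1.0, 1)


def _fit_stub(name, cost, n_params, n_data=36):
    model = make_model(name)
    p = ParameterSet(name, model.param_names, np.ones(model.n_params))
    return FitResult(model_name=name, best_params=p, best_cost=cost,
                     n_params=n_params, n_data=n_data, cutoff=49.8)


class TestLrTest:
    def test_minimized_model_worked_example(self):
        # full cost 11.2 (49 params) vs reduced 27.5 (27 params):
        # statistic 16.3 below the 33.9 cutoff at df = 22
        full = _fit_stub("Mnm1", 11.2, 49)
        reduced = _fit_stub("Mnm2", 27.5, 27)
        out = lr_test(full, reduced, alpha=0.05)
        assert out.statistic == pytest.approx(16.3)
        assert out.df == 22
        assert out.cutoff == pytest.approx(33.9, abs=0.05)
        assert out.passed

    def test_equal_costs_pass(self):
        out = lr_test(_fit_stub("Mnm1", 20.0, 49), _fit_stub("Mnm2", 20.0, 27))
        assert out.statistic == 0.0
        assert out.passed

    def test_large_cost_increase_fails(self):
        out = lr_test(_fit_stub("Mnm1", 10.0, 49), _fit_stub("Mnm2", 50.0, 27))
        assert out.statistic == pytest.approx(40.0)
        assert not out.passed

    def test_nesting_required(self):
        with pytest.raises(ValueError, match="fewer parameters"):
            lr_test(_fit_stub("Mnm2", 10.0, 27), _fit_stub("Mnm1", 20.0, 49))

    def test_same_data_required(self):
        with pytest.raises(ValueError, match="same data"):
            lr_test(_fit_stub("Mnm1", 10.0, 49),
                    _fit_stub("Mnm2", 20.0, 27, n_data=22))


class TestGlucosePlausibility:
    def test_depletion_flagged(self, fine_grid, trial):
        p = reference_parameter_set("Mm3_depleting")
        sim = simulate(make_model("Mm3"), p, trial, fine_grid)
        rep = glucose_plausibility(sim, peak_time=6.0)
        assert not rep.plausible
        assert rep.min_fraction < 0.05

    def test_moderate_early_drop_is_plausible(self, fine_grid, trial):
        # the accepted regime: glucose drops ~15 % shortly after the
        # stimulus and recovers well before the BOLD peak
        p = reference_parameter_set("Mnm2_reference")
        sim = simulate(make_model("Mnm2"), p, trial, fine_grid)
        rep = glucose_plausibility(sim, peak_time=6.25)
        assert rep.plausible
        assert 0.05 < rep.min_fraction < 1.0

    def test_minimum_coinciding_with_peak_flagged(self, fine_grid, trial):
        p = reference_parameter_set("Mnm2_reference")
        sim = simulate(make_model("Mnm2"), p, trial, fine_grid)
        g = sim.state("G")
        t_min = sim.times[np.argmin(g)]
        rep = glucose_plausibility(sim, peak_time=float(t_min))
        assert not rep.plausible

    def test_model_without_glucose_rejected(self, mn2, mn2_truth, fine_grid,
                                            trial):
        sim = simulate(mn2, mn2_truth, trial, fine_grid)
        with pytest.raises(ValueError, match="glucose"):
            glucose_plausibility(sim, peak_time=5.0)


class TestVerdict:
    def _verdict_for(self, key, cost=20.0):
        p = reference_parameter_set(key)
        model = make_model(p.model)
        grid = np.arange(-1.0, 17.51, 0.25)
        sim = simulate(model, p, single_trial(), grid)
        rep = detect_features(grid, sim.y, 0.02 * max(sim.y.max(), 1.0),
                              0.10 * max(sim.y.max(), 1.0))
        att = dip_attribution(sim, rep)
        fit = FitResult(model_name=model.name, best_params=p, best_cost=cost,
                        n_params=model.n_params, n_data=36, cutoff=49.8)
        return evaluate_model(model, fit, sim, rep, att)

    def test_feedforward_rejected_for_vasoconstrictive_dip(self):
        v = self._verdict_for("Mn2_canonical")
        assert v.chi2.passed and v.features_ok
        assert not v.plausibility_ok
        assert not v.accepted
        assert any("vasoconstrictive" in r for r in v.reasons)

    def test_extended_model_accepted(self):
        v = self._verdict_for("Mnm2_reference")
        assert v.accepted
        assert v.reasons == []

    def test_bad_fit_rejected_regardless_of_features(self):
        v = self._verdict_for("Mnm2_reference", cost=200.0)
        assert not v.accepted
        assert any("chi-square" in r for r in v.reasons)

    def test_verdict_monotone_in_alpha(self):
        # relaxing alpha (larger cutoff) never flips accepted -> rejected
        p = reference_parameter_set("Mnm2_reference")
        model = make_model("Mnm2")
        grid = np.arange(-1.0, 17.51, 0.25)
        sim = simulate(model, p, single_trial(), grid)
        rep = detect_features(grid, sim.y, 0.5, 2.5)
        att = dip_attribution(sim, rep)
        fit = FitResult(model_name="Mnm2", best_params=p, best_cost=45.0,
                        n_params=model.n_params, n_data=36, cutoff=49.8)
        accepted = [evaluate_model(model, fit, sim, rep, att, alpha=a).accepted
                    for a in (0.20, 0.10, 0.05, 0.01)]
        # once accepted at some alpha, smaller alpha (bigger cutoff) keeps it
        for earlier, later in zip(accepted, accepted[1:]):
            assert later >= earlier

    def test_table_rendering(self):
        out = Outcome(statistic=20.0, cutoff=49.8, df=35, alpha=0.05,
                      passed=True)
        v = Verdict(model_name="Mnm2", chi2=out, features_ok=True,
                    plausibility_ok=True, accepted=True)
        text = verdict_table([v])
        assert "Mnm2" in text and "accepted" in text
        csv = verdict_table([v], fmt="csv")
        assert csv.splitlines()[0].startswith("model,")
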