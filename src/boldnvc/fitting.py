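"""Chi-square cost with feature penalties, and seeded global optimization.

The cost is the sum of squared residuals between data and simulation, each
normalized by its standard error, so that under Gaussian noise the cost of the
true model follows a chi-square distribution.  Optional penalty terms force
qualitative requirements (an initial dip, a post-peak undershoot): each unmet
requirement adds ``w * (shortfall / threshold)**2`` where ``shortfall`` is the
missing depth, so the penalty vanishes continuously as the feature appears.

Optimization is a seeded, derivative-free simulated-annealing search over
log10-scaled parameters with geometric temperature decay and restarts.  Every
evaluated parameter vector whose cost passes the chi-square cutoff is archived;
the archive later feeds the core-prediction envelopes.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _minimize
from scipy.stats import chi2 as _chi2

from .models import ModelSpec, ParameterSet
from .simulate import SimulationError, detect_features, simulate
from .stimulus import Paradigm
from .timeseries import TimeSeries

__all__ = [
    "PenaltyConfig",
    "FitResult",
    "compute_cost",
    "optimize",
    "refit_for_condition",
]

logger = logging.getLogger(__name__)

#: Cost assigned to parameter sets whose simulation fails, so the search can
#: continue through rugged regions instead of aborting.
SENTINEL_COST = 1e12

#: Archive cap; beyond it the archive is thinned by cost-stratified sampling.
ARCHIVE_CAP = 5000


@dataclass
class PenaltyConfig:
    """Which qualitative features the fit must display, and how hard to push.

    Thresholds are absolute (au); ``for_data`` derives them from the
    estimation data's peak amplitude (dip 2 %, peak 10 % by default).
    """

    require_dip: bool = False
    require_undershoot: bool = False
    weight_dip: float = 100.0
    weight_undershoot: float = 100.0
    dip_threshold: float = 0.5
    peak_threshold: float = 2.5

    @classmethod
    def for_data(cls, data: TimeSeries, require_dip: bool = False,
                 require_undershoot: bool = False,
                 dip_frac: float = 0.02, peak_frac: float = 0.10,
                 **kwargs) -> "PenaltyConfig":
        peak = float(np.max(data.values))
        if peak <= 0:
            raise ValueError("data peak must be positive to scale thresholds")
        return cls(require_dip=require_dip,
                   require_undershoot=require_undershoot,
                   dip_threshold=dip_frac * peak,
                   peak_threshold=peak_frac * peak, **kwargs)

    @property
    def active(self) -> bool:
        return self.require_dip or self.require_undershoot


@dataclass
class FitResult:
    """Outcome of one optimization run."""

    model_name: str
    best_params: ParameterSet
    best_cost: float
    n_params: int
    n_data: int
    cutoff: float                     # chi-square archive cutoff used
    acceptable_archive: list = field(default_factory=list)  # [(values, cost)]
    seed: int | None = None
    budget: int = 0
    n_evaluations: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model_name,
            "best_cost": self.best_cost,
            "n_params": self.n_params,
            "n_data": self.n_data,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "budget": self.budget,
            "n_evaluations": self.n_evaluations,
            "best_params": self.best_params.as_dict(),
            "archive_size": len(self.acceptable_archive),
        }, indent=2)

    def archive_tsv(self) -> str:
        """Archive as TSV: one parameter set per row, cost column last."""
        names = self.best_params.names
        lines = ["\t".join(names) + "\tcost"]
        for values, cost in self.acceptable_archive:
            lines.append("\t".join(f"{v:.8g}" for v in values) + f"\t{cost:.8g}")
        return "\n".join(lines) + "\n"


def _penalty(report, penalties: PenaltyConfig) -> float:
    total = 0.0
    if penalties.require_dip:
        thr = penalties.dip_threshold
        achieved = report.dip_depth if report.dip_present else max(
            0.0, report.dip_depth)
        if not report.dip_present:
            shortfall = thr - min(achieved, thr)
            total += penalties.weight_dip * (shortfall / thr) ** 2
    if penalties.require_undershoot:
        thr = penalties.dip_threshold  # undershoot shares the depth threshold
        if not report.undershoot_present:
            achieved = min(report.undershoot_depth, thr)
            shortfall = thr - achieved
            total += penalties.weight_undershoot * (shortfall / thr) ** 2
    return total


def compute_cost(model: ModelSpec, p, data: TimeSeries, paradigm: Paradigm,
                 penalties: PenaltyConfig | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Chi-square cost of parameter vector ``p`` against ``data``.

    Residuals are evaluated on the data grid; a failed simulation returns the
    large sentinel cost (with a logged warning) instead of raising.
    """
    if np.any(data.sem <= 0):
        raise ValueError("all data standard errors must be positive")
    try:
        sim = simulate(model, p, paradigm, data.times, rtol=rtol, atol=atol)
        resid = (data.values - sim.y) / data.sem
        cost = float(np.dot(resid, resid))
        if penalties is not None and penalties.active:
            report = detect_features(sim.times, sim.y,
                                     penalties.dip_threshold,
                                     penalties.peak_threshold)
            cost += _penalty(report, penalties)
        if not math.isfinite(cost):
            return SENTINEL_COST
        return cost
    except (SimulationError, ValueError, FloatingPointError,
            OverflowError) as exc:
        logger.warning("simulation failed, sentinel cost assigned: %s", exc)
        return SENTINEL_COST


def _cost_scaled(model, pv, data, paradigm, penalties, iy,
                 scale_bounds, rtol, atol, mxstep):
    """Cost of ``pv`` with the linear measurement scale profiled out.

    The output is linear in ``y_scale``, so for a fixed shape the optimal
    scale solves a 1-D least-squares problem in closed form (separable /
    variable-projection step); one ODE solve still backs every evaluation.
    Returns ``(cost, pv_adjusted)`` with the profiled scale written back.
    """
    try:
        sim = simulate(model, pv, paradigm, data.times,
                       rtol=rtol, atol=atol, mxstep=mxstep)
    except (SimulationError, ValueError, FloatingPointError, OverflowError) as exc:
        logger.warning("simulation failed, sentinel cost assigned: %s", exc)
        return SENTINEL_COST, pv
    w = 1.0 / data.sem
    if iy is None or pv[iy] == 0:
        resid = (data.values - sim.y) * w
        cost = float(np.dot(resid, resid))
        y = sim.y
        pv_out = pv
    else:
        shape = sim.y / pv[iy]
        num = float(np.dot(data.values * w, shape * w))
        den = float(np.dot(shape * w, shape * w))
        if den > 0 and math.isfinite(num / den):
            scale = min(max(num / den, scale_bounds[0]), scale_bounds[1])
        else:
            scale = pv[iy]
        y = shape * scale
        resid = (data.values - y) * w
        cost = float(np.dot(resid, resid))
        pv_out = pv.copy()
        pv_out[iy] = scale
    if penalties is not None and penalties.active:
        report = detect_features(data.times, y, penalties.dip_threshold,
                                 penalties.peak_threshold)
        cost += _penalty(report, penalties)
    if not math.isfinite(cost):
        return SENTINEL_COST, pv
    return cost, pv_out


def _thin_archive(archive, cap, rng):
    """Cost-stratified thinning: keep ``cap`` sets spread across cost strata."""
    if len(archive) <= cap:
        return archive
    archive = sorted(archive, key=lambda e: e[1])
    n_strata = 10
    strata = np.array_split(np.arange(len(archive)), n_strata)
    keep_per = cap // n_strata
    kept = []
    for s in strata:
        if len(s) <= keep_per:
            kept.extend(s)
        else:
            kept.extend(rng.choice(s, size=keep_per, replace=False))
    return [archive[i] for i in sorted(kept)]


def optimize(model: ModelSpec, data: TimeSeries, paradigm: Paradigm,
             penalties: PenaltyConfig | None = None,
             seed: int = 0, budget: int = 5000,
             alpha: float = 0.05,
             n_restarts: int = 5,
             x_start: ParameterSet | None = None,
             rtol: float = 1e-6, atol: float = 1e-8) -> FitResult:
    """Seeded annealing-style global search over log10-scaled parameters.

    The proposal perturbs a random subset of coordinates; acceptance follows
    the Metropolis rule with a temperature that decays geometrically (x0.98
    every 50 evaluations).  The budget is split across ``n_restarts`` legs;
    with a warm start the first leg begins at ``x_start``.  Deterministic for
    a fixed seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = np.log10(np.array(model.param_bounds(), dtype=float))
    lo, hi = bounds[:, 0], bounds[:, 1]
    npar = model.n_params
    cutoff = float(_chi2.ppf(1.0 - alpha, data.n_points - 1))
    try:
        iy = model.param_names.index("y_scale")
        scale_bounds = model.param_bounds()[iy]
    except ValueError:
        iy, scale_bounds = None, None
    mxstep = 2000

    def evaluate(theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Cost and (scale-profiled) log-parameters of one proposal."""
        c, pv = _cost_scaled(model, 10.0 ** theta, data, paradigm, penalties,
                             iy, scale_bounds, rtol, atol, mxstep)
        if iy is not None and c < SENTINEL_COST:
            theta = theta.copy()
            theta[iy] = math.log10(max(pv[iy], 10.0 ** lo[iy]))
        return c, theta

    archive: list[tuple[np.ndarray, float]] = []
    best_theta, best_cost = None, np.inf
    n_eval = 0
    legs = max(1, min(n_restarts, budget))
    # warm starts favor exploitation: hand more of the budget to the polish
    anneal_frac = 0.3 if x_start is not None else 0.6
    anneal_budget = max(legs, int(budget * anneal_frac))  # rest goes to polish
    leg_budget = max(1, anneal_budget // legs)

    def record(theta, c):
        nonlocal best_theta, best_cost
        if c <= cutoff:
            archive.append((10.0 ** theta, c))
        if c < best_cost:
            best_theta, best_cost = theta.copy(), c
            logger.info("eval %d: improved cost to %.4g", n_eval, c)

    leg_incumbents: list[tuple[float, np.ndarray]] = []
    warm_theta, warm_cost = None, None
    for leg in range(legs):
        remaining = anneal_budget - n_eval
        if remaining <= 0:
            break
        this_budget = min(leg_budget, remaining) if leg < legs - 1 else remaining

        # screening: a handful of random starts, keep the best
        n_screen = min(max(this_budget // 20, 1), 50)
        theta, c = None, np.inf
        if leg == 0 and x_start is not None:
            theta = np.clip(np.log10(np.maximum(x_start.values, 1e-300)), lo, hi)
            c, theta = evaluate(theta)
            n_eval += 1
            record(theta, c)
            warm_theta, warm_cost = theta.copy(), c
            n_screen = 0
        for k in range(n_screen):
            if k % 2 == 0:
                # biological rate constants cluster near 1/s: half the
                # starts are drawn log-normally around that scale
                cand = np.clip(rng.normal(0.0, 1.0, npar), lo, hi)
            else:
                cand = rng.uniform(lo, hi)
            cc, cand = evaluate(cand)
            n_eval += 1
            record(cand, cc)
            if cc < c or theta is None:
                theta, c = cand, cc

        # annealing leg: Metropolis walk with geometric cooling
        T = min(max(c, 10.0), 1e4) if c < SENTINEL_COST else 1e4
        step = 0.5
        for it in range(this_budget - n_screen - (1 if x_start is not None and leg == 0 else 0)):
            if n_eval >= budget:
                break
            mask = rng.random(npar) < 0.35
            if not mask.any():
                mask[rng.integers(npar)] = True
            prop = theta.copy()
            prop[mask] += step * rng.standard_normal(int(mask.sum()))
            np.clip(prop, lo, hi, out=prop)
            c_prop, prop = evaluate(prop)
            n_eval += 1
            record(prop, c_prop)
            dc = c_prop - c
            if dc <= 0 or rng.random() < math.exp(-min(dc / max(T, 1e-12), 700)):
                theta, c = prop, c_prop
            if (it + 1) % 50 == 0:
                T *= 0.98
                step = max(0.05, step * 0.99)
            if len(archive) > 4 * ARCHIVE_CAP:
                archive = _thin_archive(archive, ARCHIVE_CAP, rng)
        if c < SENTINEL_COST and theta is not None:
            leg_incumbents.append((c, theta.copy()))

    if best_theta is None or best_cost >= SENTINEL_COST:
        raise RuntimeError(
            f"{model.name}: no finite-cost evaluation within budget {budget}")

    # derivative-free simplex polish of the best leg incumbents within the
    # remaining budget (still archive-emitting; parameters stay clipped to
    # bounds).  Multi-start polish guards against one leg's shallow basin.
    polish_budget = budget - n_eval
    if polish_budget > 2 * npar and best_cost < SENTINEL_COST:

        def nm_cost(theta):
            nonlocal n_eval
            theta = np.clip(theta, lo, hi)
            c, theta = evaluate(theta)
            n_eval += 1
            record(theta, c)
            return c

        starts = sorted(leg_incumbents, key=lambda e: e[0])[:3]
        if not any(np.array_equal(t, best_theta) for _, t in starts):
            starts = [(best_cost, best_theta.copy())] + starts[:2]
        if warm_theta is not None:
            # the caller's warm start anchors half of the polish effort
            shares = [polish_budget // (2 * max(len(starts), 1))] * len(starts)
            starts = [(warm_cost, warm_theta)] + starts
            shares = [polish_budget // 2] + shares
        else:
            shares = [polish_budget // max(len(starts) + 1, 1)] * len(starts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for (_c0, t0), share in zip(starts, shares):
                if share <= 2 * npar:
                    break
                _minimize(nm_cost, t0, method="Nelder-Mead",
                          options={"maxfev": share, "xatol": 1e-5,
                                   "fatol": 1e-8, "adaptive": npar > 8})
            # re-polish from the incumbent until the budget runs out: a
            # restarted simplex often escapes the stall of the previous one
            while budget - n_eval > max(4 * npar, 200):
                prev = best_cost
                _minimize(nm_cost, best_theta.copy(), method="Nelder-Mead",
                          options={"maxfev": budget - n_eval, "xatol": 1e-5,
                                   "fatol": 1e-8, "adaptive": npar > 8})
                if best_cost > prev - 1e-10:
                    break

    archive = _thin_archive(archive, ARCHIVE_CAP, rng)
    best = ParameterSet(model.name, model.param_names, 10.0 ** best_theta,
                        cost=best_cost, seed=seed)
    return FitResult(model_name=model.name, best_params=best,
                     best_cost=float(best_cost), n_params=npar,
                     n_data=data.n_points, cutoff=cutoff,
                     acceptable_archive=archive, seed=seed, budget=budget,
                     n_evaluations=n_eval)


def refit_for_condition(prior: FitResult, model: ModelSpec,
                        new_data: TimeSeries, paradigm: Paradigm,
                        penalties: PenaltyConfig | None = None,
                        seed: int = 0, budget: int = 5000,
                        alpha: float = 0.05) -> FitResult:
    """Re-optimize for a new condition, warm-started from ``prior``.

    Used when basal conditions change between experiments: the model is
    re-optimized on the new estimation series, starting from the previously
    found optimum, with a fresh archive and a cutoff for the new df.
    """
    if prior.model_name != model.name:
        raise ValueError(
            f"prior fit is for {prior.model_name!r}, not {model.name!r}")
    return optimize(model, new_data, paradigm, penalties=penalties, seed=seed,
                    budget=budget, alpha=alpha, x_start=prior.best_params)
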