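"""Statistical and biological model evaluation, and the verdict table.

Three criteria decide whether a model structure survives:

1. statistically acceptable agreement with the estimation data — the
   chi-square test compares the optimized cost with the inverse cumulative
   chi-square at ``df = N - 1`` (49.8 for the 36-point estimation series at
   alpha = 0.05);
2. the simulated response displays an initial dip, a peak and a post-peak
   undershoot;
3. both of the above are achieved in a biologically plausible manner — for
   structures with a glucose state, the glucose level must neither collapse
   below 5 % of basal nor reach its minimum simultaneously with the BOLD peak;
   when a dip is present it must be caused by oxygen metabolism, not by
   vasoconstriction.

Minimized (nested) structures are compared with the full structure through a
likelihood-ratio test: the cost increase of the reduced model is compared with
the chi-square quantile at ``df = n_full - n_reduced`` parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2

from .fitting import FitResult
from .models import ModelSpec
from .simulate import FeatureReport, SimulationResult

__all__ = [
    "TestOutcome",
    "Verdict",
    "chi2_cutoff",
    "chi2_test",
    "lr_test",
    "glucose_plausibility",
    "GlucoseReport",
    "evaluate_model",
    "verdict_table",
]


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    cutoff: float
    df: int
    alpha: float
    passed: bool


def chi2_cutoff(alpha: float, df: int) -> float:
    """(1 - alpha) quantile of the chi-square distribution with ``df`` dof."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return float(_chi2.ppf(1.0 - alpha, df))


def chi2_test(cost: float, n_points: int, alpha: float = 0.05) -> TestOutcome:
    """Goodness-of-fit test: pass iff ``cost <= chi2_cutoff(alpha, N - 1)``."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    if n_points < 2:
        raise ValueError("need at least 2 data points")
    df = n_points - 1
    cutoff = chi2_cutoff(alpha, df)
    return TestOutcome(statistic=float(cost), cutoff=cutoff, df=df,
                       alpha=alpha, passed=cost <= cutoff)


def lr_test(full: FitResult, reduced: FitResult,
            alpha: float = 0.05) -> TestOutcome:
    """Nested-model comparison for a minimized structure.

    The statistic is the cost increase ``V_reduced - V_full`` of the reduced
    model (the costs are already chi-square-scaled), compared with the
    chi-square quantile at ``df`` equal to the number of removed parameters.
    Passing means the minimized model is not significantly worse.
    """
    if reduced.n_params >= full.n_params:
        raise ValueError("reduced model must have fewer parameters than full")
    if reduced.n_data != full.n_data:
        raise ValueError("models must be fitted to the same data")
    df = full.n_params - reduced.n_params
    statistic = reduced.best_cost - full.best_cost
    cutoff = chi2_cutoff(alpha, df)
    return TestOutcome(statistic=float(statistic), cutoff=cutoff, df=df,
                       alpha=alpha, passed=statistic <= cutoff)


@dataclass(frozen=True)
class GlucoseReport:
    plausible: bool
    min_fraction: float   # min G / G_basal along the trajectory
    t_min: float          # time of the glucose minimum
    reasons: tuple[str, ...]


def glucose_plausibility(sim: SimulationResult, peak_time: float | None,
                         min_fraction: float = 0.05,
                         coincidence_window: float = 0.5) -> GlucoseReport:
    """Check that predicted glucose dynamics are biologically credible.

    Implausible if glucose falls below ``min_fraction`` of basal (near
    depletion) or if the glucose minimum coincides with the BOLD peak (within
    ``coincidence_window`` s) — the signature of delay states with no
    biological interpretation shaping the response.
    """
    if "G" not in sim.state_names:
        raise ValueError(f"{sim.model_name} has no glucose state")
    g = sim.state("G")
    post = sim.times > 0
    g_post = g[post] if np.any(post) else g
    t_post = sim.times[post] if np.any(post) else sim.times
    j = int(np.argmin(g_post))
    frac = float(g_post[j])  # basal glucose is normalized to 1
    t_min = float(t_post[j])
    reasons = []
    if frac < min_fraction:
        reasons.append(
            f"glucose depleted: min {frac:.3f} of basal < {min_fraction}")
    if peak_time is not None and abs(t_min - peak_time) < coincidence_window:
        reasons.append(
            f"glucose minimum at {t_min:.2f} s coincides with BOLD peak "
            f"at {peak_time:.2f} s")
    return GlucoseReport(plausible=not reasons, min_fraction=frac,
                         t_min=t_min, reasons=tuple(reasons))


@dataclass
class Verdict:
    """Acceptance/rejection of one model structure against all three criteria."""

    model_name: str
    chi2: TestOutcome
    features_ok: bool
    plausibility_ok: bool
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def evaluate_model(model: ModelSpec, fit: FitResult, sim: SimulationResult,
                   features: FeatureReport, attribution: str,
                   alpha: float = 0.05) -> Verdict:
    """Apply the three evaluation criteria and collect every failure reason."""
    reasons: list[str] = []
    outcome = chi2_test(fit.best_cost, fit.n_data, alpha)
    if not outcome.passed:
        reasons.append(
            f"chi-square fit rejected: cost {outcome.statistic:.1f} > "
            f"cutoff {outcome.cutoff:.1f} (df={outcome.df})")

    features_ok = features.all_three
    if not features_ok:
        missing = [name for name, ok in [
            ("initial dip", features.dip_present),
            ("peak", features.peak_present),
            ("post-peak undershoot", features.undershoot_present),
        ] if not ok]
        reasons.append("missing features: " + ", ".join(missing))

    plausibility_ok = True
    if model.has_glucose:
        gl = glucose_plausibility(sim, features.peak_time)
        if not gl.plausible:
            plausibility_ok = False
            reasons.extend(gl.reasons)
    if features.dip_present and attribution != "metabolic":
        plausibility_ok = False
        reasons.append(
            f"initial dip attributed to {attribution} mechanism, "
            "not oxygen metabolism")

    accepted = outcome.passed and features_ok and plausibility_ok
    return Verdict(model_name=model.name, chi2=outcome, features_ok=features_ok,
                   plausibility_ok=plausibility_ok, accepted=accepted,
                   reasons=reasons)


def verdict_table(verdicts: list[Verdict], fmt: str = "text") -> str:
    """Render verdicts as a rejection/acceptance table across structures."""
    header = ["model", "chi2_fit", "features", "plausibility", "accepted"]

    def mark(ok: bool) -> str:
        return "pass" if ok else "FAIL"

    rows = [[v.model_name, mark(v.chi2.passed), mark(v.features_ok),
             mark(v.plausibility_ok), "accepted" if v.accepted else "rejected"]
            for v in verdicts]
    if fmt == "csv":
        return "\n".join([",".join(header)] + [",".join(r) for r in rows]) + "\n"
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
    return "\n".join(lines) + "\n"
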