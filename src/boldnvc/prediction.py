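"""Core predictions with uncertainty: archive envelopes on unseen paradigms.

A core prediction is evaluated not for the single best parameter set but for
every archived parameter set that passed the chi-square acceptance test during
fitting.  Simulating the whole archive on a new paradigm and taking pointwise
minima/maxima yields an uncertainty envelope; a prediction is *uniquely
identified* when the envelope is narrow.  The envelope is a representative
selection of acceptable parameter sets, not a formal confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult
from .models import ModelSpec
from .simulate import SimulationError, simulate
from .stimulus import Paradigm
from .timeseries import TimeSeries

__all__ = [
    "PredictionEnvelope",
    "CoverageReport",
    "predict_envelope",
    "check_amplitude_ordering",
    "validate_prediction",
]


@dataclass
class PredictionEnvelope:
    """Pointwise min/best/max of the simulated output over the archive."""

    times: np.ndarray
    best: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sets: int

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.best + 1e-12)
                and np.all(self.best <= self.upper + 1e-12)):
            raise ValueError("envelope must satisfy lower <= best <= upper")

    def to_tsv(self) -> str:
        lines = ["time_s\tlower\tbest\tupper"]
        for t, lo, b, up in zip(self.times, self.lower, self.best, self.upper):
            lines.append(f"{t:.10g}\t{lo:.10g}\t{b:.10g}\t{up:.10g}")
        return "\n".join(lines) + "\n"

    def plot(self, ax=None, data: TimeSeries | None = None):
        """Best line + envelope band (+ optional data errorbars)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.times, self.lower, self.upper, alpha=0.3,
                        color="grey", label=f"envelope (n={self.n_sets})")
        ax.plot(self.times, self.best, "k-", label="best fit")
        if data is not None:
            ax.errorbar(data.times, data.values, yerr=data.sem, fmt="o",
                        ms=3, alpha=0.7, label=data.label or "data")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("BOLD (au)")
        ax.legend()
        return ax


def predict_envelope(model: ModelSpec, fit: FitResult, paradigm: Paradigm,
                     grid, max_sets: int | None = None) -> PredictionEnvelope:
    """Simulate every archived acceptable set on ``paradigm``.

    Archived sets whose simulation fails on the new paradigm are skipped (they
    no longer inform the prediction); the best-fit set must simulate.
    """
    if not fit.acceptable_archive:
        raise ValueError("fit has an empty acceptable archive")
    grid = np.asarray(grid, dtype=float)
    best_sim = simulate(model, fit.best_params, paradigm, grid)
    lower = best_sim.y.copy()
    upper = best_sim.y.copy()
    archive = fit.acceptable_archive
    if max_sets is not None and len(archive) > max_sets:
        idx = np.linspace(0, len(archive) - 1, max_sets).astype(int)
        archive = [archive[i] for i in idx]
    n_used = 1
    for values, _cost in archive:
        try:
            sim = simulate(model, values, paradigm, grid)
        except (SimulationError, ValueError):
            # sets that fail to simulate (or lose a defined output, e.g.
            # dHb hitting zero) on the new paradigm cannot inform it
            continue
        np.minimum(lower, sim.y, out=lower)
        np.maximum(upper, sim.y, out=upper)
        n_used += 1
    return PredictionEnvelope(times=grid, best=best_sim.y, lower=lower,
                              upper=upper, n_sets=n_used)


def check_amplitude_ordering(envelopes: list[tuple[float, PredictionEnvelope]]
                             ) -> bool:
    """True iff the best-trace peak decreases strictly with input amplitude.

    ``envelopes`` pairs each input amplitude with its prediction envelope; at
    least two distinct amplitudes are required.
    """
    if len(envelopes) < 2:
        raise ValueError("need at least 2 envelopes to check ordering")
    amps = [a for a, _ in envelopes]
    if len(set(amps)) != len(amps):
        raise ValueError("input amplitudes must be distinct")
    ordered = sorted(envelopes, key=lambda e: -e[0])
    peaks = [float(np.max(env.best)) for _, env in ordered]
    return all(peaks[i] > peaks[i + 1] for i in range(len(peaks) - 1))


@dataclass
class CoverageReport:
    """How well validation data fall inside a prediction envelope."""

    coverage: float          # fraction of data +-1 SE intervals hitting envelope
    n_points: int
    data_n_peaks: int
    predicted_n_peaks: int
    peaks_agree: bool
    passed: bool             # coverage >= threshold

    threshold: float = 0.8


def validate_prediction(envelope: PredictionEnvelope, data: TimeSeries,
                        coverage_threshold: float = 0.8,
                        peak_threshold_frac: float = 0.10) -> CoverageReport:
    """Compare a core-prediction envelope with held-out validation data.

    Reports the fraction of data points whose +-1 SE interval intersects
    [lower, upper] (envelope linearly resampled onto the data grid), plus peak
    count agreement between the data and the best trace.
    """
    t0, t1 = envelope.times[0], envelope.times[-1]
    mask = (data.times >= t0) & (data.times <= t1)
    if not np.any(mask):
        raise ValueError("data grid does not overlap the envelope grid")
    t = data.times[mask]
    v = data.values[mask]
    s = data.sem[mask]
    lo = np.interp(t, envelope.times, envelope.lower)
    up = np.interp(t, envelope.times, envelope.upper)
    hit = (v + s >= lo) & (v - s <= up)
    coverage = float(np.mean(hit))

    from .simulate import detect_features

    peak_amp = float(np.max(v))
    thr = max(peak_threshold_frac * abs(peak_amp), 1e-9)
    data_feat = detect_features(t, v, dip_threshold=thr * 0.2,
                                peak_threshold=thr)
    pred_feat = detect_features(envelope.times, envelope.best,
                                dip_threshold=thr * 0.2, peak_threshold=thr)
    return CoverageReport(coverage=coverage, n_points=int(mask.sum()),
                          data_n_peaks=data_feat.n_peaks,
                          predicted_n_peaks=pred_feat.n_peaks,
                          peaks_agree=data_feat.n_peaks == pred_feat.n_peaks,
                          passed=coverage >= coverage_threshold,
                          threshold=coverage_threshold)
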