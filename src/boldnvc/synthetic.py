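"""Synthetic group-level BOLD data with the study's statistical structure.

The generator emulates event-related group-mean responses from 12 subjects
sampled at TR = 0.5 s over a window of -1 to 17.5 s (38 samples, of which 36
are post-onset, so the goodness-of-fit test runs at df = 35): a smooth ground
truth (a fitted model or a canonical double-gamma response peaking near 6 s
with amplitude ~20-25 au and a post-peak undershoot) plus i.i.d. Gaussian
per-subject noise.  The group mean and standard error (sample SD / sqrt(n))
are baseline-normalized exactly like acquired data, by subtracting the last
pre-stimulus sample.

Defaults reproduce the study conditions: n = 12 subjects, intensity-experiment
peak 23.5 au, and a noise SD chosen so the group SE is ~10 % of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import gamma as _gamma

from .models import ModelSpec, ParameterSet
from .simulate import simulate
from .stimulus import Paradigm, single_trial
from .timeseries import TimeSeries, baseline_normalize

__all__ = [
    "SyntheticSpec",
    "canonical_hrf",
    "generate_group_bold",
    "study_intensity_truth",
    "study_frequency_truth",
]

#: Floor applied to standard errors so noise-free fixtures never divide by 0.
SE_FLOOR = 1e-6

#: Peak amplitudes of the group-mean primary-stimulus responses that the
#: generator emulates (intensity and frequency experiments, au).
INTENSITY_PEAK_AU = 23.5
FREQUENCY_PEAK_AU = 19.8

#: Default per-subject noise SD (au).  With 12 subjects this puts the group
#: SE near 10 % of the intensity peak, matching the visual relative error of
#: the measured estimation series.
DEFAULT_NOISE_SD = 8.0


def canonical_hrf(t, peak_time: float = 6.0, undershoot_time: float = 12.0,
                  ratio: float = 0.15):
    """Model-free canonical BOLD response: difference of two gamma densities.

    Scaled to unit peak; zero for t <= 0.  ``ratio`` sets the undershoot lobe
    relative to the (unit-peak) positive lobe; ``ratio = 0`` removes it.
    """
    if peak_time <= 0 or undershoot_time <= 0:
        raise ValueError("peak_time and undershoot_time must be positive")
    if peak_time >= undershoot_time:
        raise ValueError("peak_time must precede undershoot_time")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    t = np.asarray(t, dtype=float)
    a1, a2 = 7.0, 13.0
    th1 = peak_time / (a1 - 1.0)
    th2 = undershoot_time / (a2 - 1.0)
    g1 = _gamma.pdf(t, a1, scale=th1)
    g2 = _gamma.pdf(t, a2, scale=th2)
    g1 /= _gamma.pdf(peak_time, a1, scale=th1)
    if ratio > 0:
        g2 /= _gamma.pdf(undershoot_time, a2, scale=th2)
    h = g1 - ratio * g2
    h = h / np.max(h) if np.max(h) > 0 else h
    h = np.where(t <= 0, 0.0, h)
    if h.ndim == 0:
        return float(h)
    return h


def study_intensity_truth(amplitude: float = INTENSITY_PEAK_AU
                          ) -> Callable[[np.ndarray], np.ndarray]:
    """Ground truth emulating the intensity-experiment primary stimulus."""
    return lambda t: amplitude * canonical_hrf(t)


def study_frequency_truth(amplitude: float = FREQUENCY_PEAK_AU
                          ) -> Callable[[np.ndarray], np.ndarray]:
    """Ground truth emulating the frequency-experiment primary stimulus."""
    return lambda t: amplitude * canonical_hrf(t)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic group-mean series.

    ``ground_truth`` is either a callable t -> au, or a (model, params) pair
    simulated under ``paradigm``.
    """

    ground_truth: Callable | tuple[ModelSpec, ParameterSet]
    n_subjects: int = 12
    noise_sd: float = DEFAULT_NOISE_SD
    tr: float = 0.5
    window: tuple[float, float] = (-1.0, 17.5)
    seed: int = 0
    paradigm: Paradigm = field(default_factory=single_trial)
    label: str = "synthetic"

    def grid(self) -> np.ndarray:
        n = int(round((self.window[1] - self.window[0]) / self.tr)) + 1
        return self.window[0] + self.tr * np.arange(n)


def generate_group_bold(spec: SyntheticSpec
                        ) -> tuple[TimeSeries, np.ndarray]:
    """Generate one group-mean series plus the per-subject traces.

    Per subject s: trace_s(t) = truth(t) + eps_s(t) with eps i.i.d.
    Gaussian(0, noise_sd).  Each subject trace is baseline-normalized (its
    last pre-stimulus sample subtracted) before averaging, mirroring how the
    acquired responses were processed; the inter-subject standard error
    therefore includes the baseline-subtraction noise.  Returns the group
    mean (SE = sample SD / sqrt(n), floored at 1e-6 au) and the
    (n_subjects, n_times) array of normalized subject traces.
    """
    if spec.n_subjects < 2:
        raise ValueError("need at least 2 subjects to define a standard error")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = spec.grid()
    if callable(spec.ground_truth):
        truth = np.asarray(spec.ground_truth(t), dtype=float)
    else:
        model, params = spec.ground_truth
        truth = simulate(model, params, spec.paradigm, t).y
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_subjects, len(t)))
    subjects = truth[None, :] + noise
    pre = np.nonzero(t < 0)[0]
    if len(pre) == 0:
        raise ValueError("window must contain at least one pre-stimulus sample")
    subjects = subjects - subjects[:, [pre[-1]]]
    mean = subjects.mean(axis=0)
    se = subjects.std(axis=0, ddof=1) / np.sqrt(spec.n_subjects)
    se = np.maximum(se, SE_FLOOR)
    ts = TimeSeries(times=t, values=mean, sem=se, label=spec.label)
    return baseline_normalize(ts, stim_onset=0.0), subjects
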