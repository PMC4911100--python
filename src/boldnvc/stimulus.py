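"""Visual stimulation paradigms and the model input u(t).

The study's two event-related designs are reconstructed here:

* the *intensity* experiment — circles at three luminances (white, light grey,
  dark grey), each shown 9 times for 500 ms with an inter-trial interval (ITI)
  jittered in 18–20 s: 27 trials in total;
* the *frequency* experiment — white circles presented either singly or as a
  pair with an inter-pair interval (IPI) of 1 s or 4 s, 8 trials per mode with
  an ITI of 19–21 s: 24 trials (a paired trial contributes two 0.5 s pulses).

The input to every ODE model is u(t) = sum of boxcar pulses, one per event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEvent",
    "Paradigm",
    "build_intensity_paradigm",
    "build_frequency_paradigm",
    "single_trial",
    "paired_trial",
    "evaluate_input",
]

#: Default pulse duration: the circles were shown for 500 ms.
DEFAULT_DURATION = 0.5

#: Default relative luminances.  The true intensities of the grey stimuli were
#: not known experimentally; these values are used only for qualitative
#: amplitude-ordering predictions.
INTENSITY_AMPLITUDES = (1.0, 0.6, 0.3)  # white, light grey, dark grey


@dataclass(frozen=True)
class StimulusEvent:
    """One boxcar pulse of the visual input."""

    onset: float
    duration: float = DEFAULT_DURATION
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("event amplitude must be >= 0")


@dataclass(frozen=True)
class Paradigm:
    """An ordered sequence of stimulus events.

    ``n_trials`` counts experimental trials; a paired trial contributes two
    events but one trial.
    """

    events: tuple[StimulusEvent, ...]
    total_duration: float
    name: str = ""
    n_trials: int | None = None

    def __post_init__(self) -> None:
        ev = tuple(sorted(self.events, key=lambda e: e.onset))
        if ev and ev[0].onset < 0:
            raise ValueError("event onsets must be non-negative")
        object.__setattr__(self, "events", ev)
        if self.n_trials is None:
            object.__setattr__(self, "n_trials", len(ev))

    @property
    def n_events(self) -> int:
        return len(self.events)

    def edge_times(self) -> np.ndarray:
        """Sorted pulse on/off times (solver critical points)."""
        edges = set()
        for e in self.events:
            edges.add(e.onset)
            edges.add(e.onset + e.duration)
        return np.array(sorted(edges))

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "total_duration": self.total_duration,
                "n_trials": self.n_trials,
                "events": [
                    {"onset": e.onset, "duration": e.duration, "amplitude": e.amplitude}
                    for e in self.events
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Paradigm":
        d = json.loads(text)
        return cls(
            events=tuple(StimulusEvent(**e) for e in d["events"]),
            total_duration=d["total_duration"],
            name=d.get("name", ""),
            n_trials=d.get("n_trials"),
        )


def build_intensity_paradigm(
    amplitudes: tuple[float, float, float] = INTENSITY_AMPLITUDES,
    iti_range: tuple[float, float] = (18.0, 20.0),
    reps: int = 9,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    lead_in: float = 10.0,
) -> Paradigm:
    """Intensity experiment: ``reps`` presentations per luminance, order
    randomized by ``seed``, ITI drawn uniformly from ``iti_range``.
    """
    if iti_range[0] > iti_range[1]:
        raise ValueError("iti_range min must not exceed max")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (amplitudes[0] >= amplitudes[1] >= amplitudes[2]):
        raise ValueError("amplitudes must be ordered white >= light grey >= dark grey")
    rng = np.random.default_rng(seed)
    amps = np.repeat(np.asarray(amplitudes, dtype=float), reps)
    rng.shuffle(amps)
    events = []
    t = lead_in
    for a in amps:
        events.append(StimulusEvent(onset=t, duration=duration, amplitude=float(a)))
        t += float(rng.uniform(*iti_range))
    return Paradigm(
        events=tuple(events),
        total_duration=t + 20.0,
        name="intensity",
        n_trials=len(events),
    )


def build_frequency_paradigm(
    ipi_values: tuple[float, ...] = (1.0, 4.0),
    iti_range: tuple[float, float] = (19.0, 21.0),
    reps: int = 8,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    amplitude: float = 1.0,
    lead_in: float = 10.0,
) -> Paradigm:
    """Frequency experiment: single and paired (per IPI) trials, ``reps`` each.

    A paired trial emits two ``duration``-long pulses separated by the IPI.
    """
    if iti_range[0] > iti_range[1]:
        raise ValueError("iti_range min must not exceed max")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for ipi in ipi_values:
        if ipi < duration:
            raise ValueError(
                f"IPI {ipi} s overlaps the {duration} s pulse (overlapping pulses)"
            )
    rng = np.random.default_rng(seed)
    # modes: None = single, otherwise the IPI of a paired trial
    modes: list[float | None] = [None] * reps
    for ipi in ipi_values:
        modes += [float(ipi)] * reps
    order = rng.permutation(len(modes))
    events = []
    n_trials = 0
    t = lead_in
    for idx in order:
        ipi = modes[idx]
        events.append(StimulusEvent(onset=t, duration=duration, amplitude=amplitude))
        if ipi is not None:
            events.append(
                StimulusEvent(onset=t + ipi, duration=duration, amplitude=amplitude)
            )
        n_trials += 1
        t += float(rng.uniform(*iti_range))
    return Paradigm(
        events=tuple(events),
        total_duration=t + 20.0,
        name="frequency",
        n_trials=n_trials,
    )


def single_trial(
    amplitude: float = 1.0,
    duration: float = DEFAULT_DURATION,
    onset: float = 0.0,
    total_duration: float = 20.0,
    name: str = "single_trial",
) -> Paradigm:
    """One isolated pulse: the paradigm a mean single-trial response is fit on."""
    return Paradigm(
        events=(StimulusEvent(onset=onset, duration=duration, amplitude=amplitude),),
        total_duration=total_duration,
        name=name,
        n_trials=1,
    )


def paired_trial(
    ipi: float,
    amplitude: float = 1.0,
    duration: float = DEFAULT_DURATION,
    onset: float = 0.0,
    total_duration: float = 25.0,
    name: str = "paired_trial",
) -> Paradigm:
    """One paired presentation: two pulses separated by ``ipi`` seconds."""
    if ipi < duration:
        raise ValueError(f"IPI {ipi} s overlaps the {duration} s pulse")
    return Paradigm(
        events=(
            StimulusEvent(onset=onset, duration=duration, amplitude=amplitude),
            StimulusEvent(onset=onset + ipi, duration=duration, amplitude=amplitude),
        ),
        total_duration=total_duration,
        name=name,
        n_trials=1,
    )


def evaluate_input(paradigm: Paradigm, t: float | np.ndarray):
    """u(t) = sum over events of amplitude * 1[onset <= t < onset + duration].

    Overlapping pulses add.  Accepts a scalar or an array of times.
    """
    t_arr = np.asarray(t, dtype=float)
    u = np.zeros_like(t_arr, dtype=float)
    for e in paradigm.events:
        u += e.amplitude * ((t_arr >= e.onset) & (t_arr < e.onset + e.duration))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(u)
    return u
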