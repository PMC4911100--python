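"""Group-mean BOLD time series: container, plain-text I/O and baseline normalization.

A :class:`TimeSeries` holds the sampled group-mean BOLD signal ``y(t_i)`` with the
per-time-point standard error ``sigma(t_i)`` that later normalizes the residuals
of the chi-square cost.  Two plain-text dialects are supported:

* *block* dialect — one block per condition, a ``# label`` header line followed
  by three whitespace-delimited numeric columns (time_s, mean_au, se_au);
* *wide* dialect — a single header line naming a time column plus
  ``<label>_mean`` / ``<label>_se`` column pairs, one pair per condition.

The dialect is auto-detected from the first non-comment line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimeSeries",
    "BoldParseError",
    "read_bold_series",
    "read_bold_file",
    "write_bold_series",
    "baseline_normalize",
]


class BoldParseError(ValueError):
    """Raised when a BOLD series file violates the format contract."""


@dataclass(frozen=True)
class TimeSeries:
    """Sampled group-mean BOLD signal with per-point standard errors.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing.  Times are absolute
        seconds relative to stimulus onset at t = 0; pre-onset samples carry
        negative times.
    values : ndarray
        BOLD signal in arbitrary units (au).
    sem : ndarray
        Standard error of the group mean per time point, au, all > 0.
    label : str
        Condition identifier, e.g. ``"intensity_primary"``.
    """

    times: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.sem, dtype=float)
        if not (t.ndim == v.ndim == s.ndim == 1):
            raise ValueError("times, values and sem must be 1-D")
        if not (len(t) == len(v) == len(s)):
            raise ValueError("times, values and sem must have identical length")
        if len(t) < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(s > 0):
            raise ValueError("all standard errors must be strictly positive")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v)) and np.all(np.isfinite(s))):
            raise ValueError("times, values and sem must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sem", s)

    @property
    def n_points(self) -> int:
        return len(self.times)

    def window(self, t_min: float, t_max: float) -> "TimeSeries":
        """Restrict to samples with ``t_min <= t <= t_max``."""
        m = (self.times >= t_min) & (self.times <= t_max)
        if m.sum() < 2:
            raise ValueError("window keeps fewer than 2 samples")
        return TimeSeries(self.times[m], self.values[m], self.sem[m], self.label)


def _parse_float(token: str, lineno: int, path: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise BoldParseError(
            f"{path}:{lineno}: non-numeric cell {token!r}"
        ) from None


def _finish_block(label, ts_rows, path, start_line, out):
    if not ts_rows:
        return
    arr = np.array(ts_rows, dtype=float)
    t, v, s = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(np.diff(t) <= 0):
        i = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise BoldParseError(
            f"{path}:{start_line + i + 1}: non-increasing time at t={t[i + 1]}"
        )
    if np.any(s <= 0):
        i = int(np.nonzero(s <= 0)[0][0])
        raise BoldParseError(
            f"{path}:{start_line + i}: non-positive SE {s[i]}"
        )
    out[label] = TimeSeries(t, v, s, label)


def read_bold_file(path: str) -> dict[str, TimeSeries]:
    """Read every condition in a BOLD series file; dialect auto-detected.

    Returns a dict mapping condition label to :class:`TimeSeries`, preserving
    file order (dicts are insertion-ordered).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    # Find the first contentful line to sniff the dialect.
    first = None
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        first = stripped
        break
    if first is None:
        raise BoldParseError(f"{path}: file contains no data")

    tokens = first.split()
    numeric_first = True
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            numeric_first = False
            break

    if numeric_first:
        return _read_block_dialect(lines, path)
    return _read_wide_dialect(lines, path)


def _read_block_dialect(lines, path) -> dict[str, TimeSeries]:
    out: dict[str, TimeSeries] = {}
    label = "series"
    rows: list[tuple[float, float, float]] = []
    block_start = 1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body:  # "# label" starts a new block; bare '#' is a comment
                _finish_block(label, rows, path, block_start, out)
                label, rows, block_start = body, [], lineno + 1
            continue
        cols = line.split()
        if len(cols) < 3:
            raise BoldParseError(
                f"{path}:{lineno}: expected 3 columns (time, mean, SE), got {len(cols)}"
            )
        if not rows:
            block_start = lineno
        rows.append(tuple(_parse_float(c, lineno, path) for c in cols[:3]))
    _finish_block(label, rows, path, block_start, out)
    if not out:
        raise BoldParseError(f"{path}: no data rows found")
    return out


def _read_wide_dialect(lines, path) -> dict[str, TimeSeries]:
    header = None
    data_rows = []
    header_line = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split()
            header_line = lineno
            continue
        cols = line.split()
        if len(cols) != len(header):
            raise BoldParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cols)}"
            )
        data_rows.append([_parse_float(c, lineno, path) for c in cols])
    if header is None or not data_rows:
        raise BoldParseError(f"{path}: no data rows found")

    names = [h.lower() for h in header]
    try:
        t_idx = next(i for i, n in enumerate(names) if n in ("time", "time_s", "t"))
    except StopIteration:
        raise BoldParseError(f"{path}:{header_line}: missing time column") from None

    arr = np.array(data_rows, dtype=float)
    t = arr[:, t_idx]
    if np.any(np.diff(t) <= 0):
        i = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise BoldParseError(f"{path}: non-increasing time at row {i + 2}")

    out: dict[str, TimeSeries] = {}
    for i, name in enumerate(names):
        if name.endswith("_mean"):
            label = header[i][: -len("_mean")]
            se_name = name[: -len("_mean")] + "_se"
            if se_name not in names:
                raise BoldParseError(
                    f"{path}:{header_line}: missing SE column for condition {label!r}"
                )
            j = names.index(se_name)
            s = arr[:, j]
            if np.any(s <= 0):
                k = int(np.nonzero(s <= 0)[0][0])
                raise BoldParseError(
                    f"{path}: non-positive SE for {label!r} at row {k + 2}"
                )
            out[label] = TimeSeries(t, arr[:, i], s, label)
    if not out:
        raise BoldParseError(f"{path}:{header_line}: no <label>_mean columns found")
    return out


def read_bold_series(path: str, label: str | None = None) -> TimeSeries:
    """Read one condition from a BOLD series file.

    With ``label=None`` the first condition in the file is returned.
    """
    series = read_bold_file(path)
    if label is None:
        return next(iter(series.values()))
    if label not in series:
        raise BoldParseError(
            f"{path}: no condition {label!r}; available: {sorted(series)}"
        )
    return series[label]


def write_bold_series(ts: TimeSeries, path: str) -> None:
    """Write a TimeSeries in the block dialect (round-trips to >=6 s.f.)."""
    buf = io.StringIO()
    buf.write(f"# {ts.label or 'series'}\n")
    for t, v, s in zip(ts.times, ts.values, ts.sem):
        buf.write(f"{t:.10g}\t{v:.10g}\t{s:.10g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def baseline_normalize(ts: TimeSeries, stim_onset: float = 0.0) -> TimeSeries:
    """Shift values so the last sample strictly before ``stim_onset`` is 0.

    Mirrors the normalization applied to the acquired responses: the signal
    value of the last time point before the stimulation is subtracted from the
    whole time course.  Standard errors are unchanged.  Idempotent.
    """
    pre = np.nonzero(ts.times < stim_onset)[0]
    if len(pre) == 0:
        raise ValueError(
            f"no sample before stimulus onset {stim_onset}; first time is {ts.times[0]}"
        )
    ref = ts.values[pre[-1]]
    return replace(ts, values=ts.values - ref)
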