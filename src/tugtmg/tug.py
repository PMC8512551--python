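"""Segmentation of Timed Up-and-Go distance-over-time signals into subtask times.

A chair-mounted distance sensor records how far the participant is from the
chair, nominally at 10 Hz.  The test decomposes into five subtasks delimited
by distance bands: sit-up / sit-down in 0–0.99 m, walk-forward / walk-back in
1.00–3.19 m, and the turnaround at 3.20–3.50 m.  This module cleans a raw
recording, finds the seated start and end of the test, and converts the
distance trajectory into the five subtask durations plus the total time.

Boundary crossings are located by linear interpolation between the straddling
samples (local least-squares fits when the recording is measurably noisy),
with a Schmitt-trigger hysteresis so that sensor noise around a band boundary
does not produce spurious crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DistanceSignal",
    "BandConfig",
    "SubtaskTimes",
    "SegmentationError",
    "preprocess",
    "detect_start",
    "detect_end",
    "segment",
    "analyze_tug",
]

#: Names of the five subtasks in chronological order.
SUBTASKS = ("sit_up", "walk_forward", "turn", "walk_back", "sit_down")


#: noise scale (m) above which crossings switch to local least-squares fits
_REFINE_NOISE_M = 0.005


class SegmentationError(ValueError):
    """A distance signal that cannot be segmented into a valid TUG test."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(f"{reason}: {message}" if message else reason)


@dataclass
class DistanceSignal:
    """One TUG recording: distance from the sensor sampled over time.

    Parameters
    ----------
    time_s : array-like
        Sample timestamps in seconds, strictly increasing, nominally 10 Hz.
    distance_m : array-like
        Distance from the sensor in metres.  Raw recordings may contain
        non-finite or out-of-range readings (dropouts); :func:`preprocess`
        repairs them.
    meta : dict
        Free-form identifiers (participant, test index, ...).
    """

    time_s: np.ndarray
    distance_m: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.distance_m = np.asarray(self.distance_m, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.distance_m.shape:
            raise ValueError("time_s and distance_m must be 1-D arrays of equal length")
        if self.time_s.size < 2:
            raise ValueError("a distance signal needs at least 2 samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def sample_period_s(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class BandConfig:
    """Distance bands and detection options for subtask segmentation.

    The defaults are the bands established for the chair-mounted ultrasonic
    device: sit phases in 0–0.99 m, walking in 1.00–3.19 m, turnaround in
    3.20–3.50 m, with the seated start/end criterion at <0.10 m.  The 1 cm
    gaps between printed band edges are treated as single boundaries at their
    midpoints (0.995 m and 3.195 m) — the bands are contiguous labels, not
    dead zones.
    """

    sit_band: tuple[float, float] = (0.0, 0.99)
    walk_band: tuple[float, float] = (1.00, 3.19)
    turn_band: tuple[float, float] = (3.20, 3.50)
    start_threshold_m: float = 0.10
    #: Schmitt-trigger margin; must exceed the 3 cm sensor resolution.
    hysteresis_m: float = 0.05
    #: Running-median window (odd sample count) applied by :func:`preprocess`.
    smoothing_window: int = 3
    #: Readings outside [0, sensor_range_m] are treated as dropouts.
    sensor_range_m: float = 6.0
    #: Minimum seated dwell for the start/end criterion, seconds.
    min_seated_s: float = 1.0
    #: Fraction of invalid samples above which a recording is rejected.
    max_invalid_fraction: float = 0.20

    def __post_init__(self):
        if not (0 < self.start_threshold_m < self.sit_band[1]):
            raise ValueError("start_threshold_m must lie inside the sit band")
        if not (self.sit_band[1] <= self.walk_band[0] <= self.walk_band[1] <= self.turn_band[0]):
            raise ValueError("bands must be contiguous and non-overlapping")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.hysteresis_m < 0:
            raise ValueError("hysteresis_m must be non-negative")

    @property
    def sit_walk_boundary_m(self) -> float:
        """Effective sit/walk boundary (midpoint of the printed band gap)."""
        return 0.5 * (self.sit_band[1] + self.walk_band[0])

    @property
    def walk_turn_boundary_m(self) -> float:
        """Effective walk/turn boundary (midpoint of the printed band gap)."""
        return 0.5 * (self.walk_band[1] + self.turn_band[0])


@dataclass
class SubtaskTimes:
    """The five TUG subtask durations plus the total test time (seconds).

    ``boundary_times_s`` holds the six segmentation instants on the
    recording's own time axis: test start, the four interior band crossings,
    and test end.  The five durations telescope between consecutive
    boundaries, so they sum to ``total_s`` exactly.
    """

    sit_up_s: float
    walk_forward_s: float
    turn_s: float
    walk_back_s: float
    sit_down_s: float
    total_s: float
    boundary_times_s: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def durations(self) -> dict:
        """The five subtask durations keyed by subtask name."""
        return {
            "sit_up": self.sit_up_s,
            "walk_forward": self.walk_forward_s,
            "turn": self.turn_s,
            "walk_back": self.walk_back_s,
            "sit_down": self.sit_down_s,
        }

    def as_dict(self) -> dict:
        d = {f"{k}_s": v for k, v in self.durations().items()}
        d["total_s"] = self.total_s
        d["boundary_times_s"] = dict(self.boundary_times_s)
        d["flags"] = list(self.flags)
        return d


# ---------------------------------------------------------------------------
# crossing machinery
# ---------------------------------------------------------------------------

def _noise_scale(x: np.ndarray) -> float:
    """Robust noise estimate from second differences (zero for noiseless data).

    Piecewise-linear and flat stretches have exactly zero second difference,
    so smooth trajectories report ~0 while sensor noise reports its SD.
    """
    d2 = np.diff(x, n=2)
    if d2.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


def _interp_crossing(t: np.ndarray, x: np.ndarray, j: int, level: float) -> float:
    """Linearly interpolated time at which x crosses `level` between j and j+1."""
    x0, x1 = x[j], x[j + 1]
    return float(t[j] + (level - x0) / (x1 - x0) * (t[j + 1] - t[j]))


_FIT_SIDE_SAMPLES = 8


def _fit_crossing(t: np.ndarray, x: np.ndarray, j: int, level: float, direction: int) -> float:
    """Crossing time from local least-squares lines fitted on each side of j.

    The trajectory may change slope exactly at a band boundary, so a single
    straddling fit would be biased; instead each side gets its own line, each
    line yields its own crossing of ``level``, and the two estimates are
    combined with inverse-variance weights (steeper, better-determined sides
    dominate).  Falls back to two-point interpolation if neither side gives a
    slope in the crossing direction.  The estimate is clamped to the fit
    window.
    """
    lo = max(0, j - _FIT_SIDE_SAMPLES + 1)
    hi = min(x.size, j + 1 + _FIT_SIDE_SAMPLES)
    estimates, weights = [], []
    for tt, xx in ((t[lo : j + 1], x[lo : j + 1]), (t[j + 1 : hi], x[j + 1 : hi])):
        if tt.size < 2:
            continue
        slope, intercept = np.polyfit(tt, xx, 1)
        if direction * slope <= 1e-9:
            continue
        tc = (level - intercept) / slope
        tbar = tt.mean()
        stt = float(((tt - tbar) ** 2).sum())
        if stt <= 0:
            continue
        var = (1.0 / tt.size + (tc - tbar) ** 2 / stt) / (slope * slope)
        if np.isfinite(var) and var > 0:
            estimates.append(tc)
            weights.append(1.0 / var)
    if not estimates:
        return _interp_crossing(t, x, j, level)
    tc = float(np.average(estimates, weights=weights))
    return float(min(max(tc, t[lo]), t[hi - 1]))


def _schmitt_events(
    t: np.ndarray,
    x: np.ndarray,
    level: float,
    hysteresis: float,
    below_at_level: bool = False,
    refine: bool = False,
) -> tuple[list[tuple[float, int]], int]:
    """Hysteresis threshold crossings of ``level``.

    A rising event fires when the signal, previously below, reaches
    ``level + hysteresis``; a falling event when, previously above, it falls
    to ``level - hysteresis`` — or strictly below ``level`` itself when
    ``below_at_level`` is set (used for the seated-start criterion
    "distance < threshold", whose seated level may sit inside a symmetric
    hysteresis band).  Each event's time is the crossing of ``level`` at the
    straddling sample pair: linear interpolation, or a local least-squares
    fit when ``refine`` is set (noisy signals).

    Returns
    -------
    events : list of (time, direction)
        direction is +1 for rising, -1 for falling, in chronological order.
    initial_state : int
        +1 if the signal starts at/above ``level``, else -1.
    """
    if refine:
        # averaging a little before thresholding steadies the trigger and the
        # straddle placement under quantized noise
        x = ndimage.uniform_filter1d(x, size=3, mode="nearest")
    hi = level + hysteresis
    definite = np.zeros(x.size, dtype=np.int8)
    definite[x >= hi] = 1
    if below_at_level:
        definite[x < level] = -1
    else:
        definite[x <= level - hysteresis] = -1
    initial_state = 1 if x[0] >= level else -1

    locate = _fit_crossing if refine else (lambda t, x, j, lv, d: _interp_crossing(t, x, j, lv))
    events: list[tuple[float, int]] = []
    state = initial_state
    for i in np.flatnonzero(definite):
        s = int(definite[i])
        if s == state:
            continue
        if s > 0:  # rising: find last sample below `level` before i
            j = i
            while j > 0 and x[j] >= level:
                j -= 1
            if x[j] < level:
                events.append((locate(t, x, j, level, +1), +1))
        else:  # falling
            j = i
            while j > 0 and x[j] <= level:
                j -= 1
            if x[j] > level:
                events.append((locate(t, x, j, level, -1), -1))
        state = s
    return events, initial_state


def _below_runs(
    t: np.ndarray, events: Sequence[tuple[float, int]], initial_state: int
) -> list[tuple[float, float]]:
    """Intervals during which the Schmitt state is 'below', as (t_from, t_to).

    ``t_to`` is the rising-event time ending the run, or the final sample
    time if the signal ends while still below.
    """
    runs = []
    state = initial_state
    t_from = t[0] if initial_state < 0 else None
    for ev_t, ev_dir in events:
        if ev_dir < 0 and state > 0:
            t_from = ev_t
        elif ev_dir > 0 and state < 0 and t_from is not None:
            runs.append((t_from, ev_t))
            t_from = None
        state = ev_dir
    if t_from is not None:
        runs.append((t_from, float(t[-1])))
    return runs


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def preprocess(signal: DistanceSignal, config: BandConfig = BandConfig()) -> DistanceSignal:
    """Repair dropouts and smooth a raw recording.

    Non-finite readings and readings outside the sensor range are replaced by
    linear interpolation between valid neighbours (edge dropouts take the
    nearest valid value), then an odd-window running median is applied.
    Timestamps are unchanged.

    Raises
    ------
    SegmentationError
        reason ``"unusable signal"`` if more than ``max_invalid_fraction``
        of the samples are invalid.
    """
    t = signal.time_s
    x = signal.distance_m.astype(float).copy()
    invalid = ~np.isfinite(x) | (x < 0.0) | (x > config.sensor_range_m)
    frac = invalid.mean()
    if frac > config.max_invalid_fraction:
        raise SegmentationError(
            "unusable signal",
            f"{frac:.0%} of samples invalid (> {config.max_invalid_fraction:.0%} allowed)",
        )
    if invalid.all():
        raise SegmentationError("unusable signal", "no valid samples")
    if invalid.any():
        valid = ~invalid
        x[invalid] = np.interp(t[invalid], t[valid], x[valid])
    if config.smoothing_window > 1:
        x = ndimage.median_filter(x, size=config.smoothing_window, mode="nearest")
    meta = dict(signal.meta)
    meta["n_interpolated"] = int(invalid.sum())
    return DistanceSignal(time_s=t, distance_m=x, meta=meta)


def detect_start(signal: DistanceSignal, config: BandConfig = BandConfig()) -> float:
    """Time at which the test starts (end of the seated period), in seconds.

    The participant must sit within ``start_threshold_m`` of the sensor for at
    least ``min_seated_s`` before rising.  The start is the interpolated
    upward crossing of the threshold that terminates that seated run and is
    followed by a sustained rise (the excursion that reaches the sit/walk
    boundary, when the recording contains one).

    Raises
    ------
    SegmentationError
        reason ``"no seated start detected"`` if the signal never sits below
        the threshold for long enough before rising.
    """
    t, x = signal.time_s, signal.distance_m
    cfg = config
    if not np.any(x < cfg.start_threshold_m):
        raise SegmentationError("no seated start detected", "signal never below start threshold")
    refine = _noise_scale(x) > _REFINE_NOISE_M
    events, init = _schmitt_events(
        t, x, cfg.start_threshold_m, cfg.hysteresis_m, below_at_level=True, refine=refine
    )
    runs = _below_runs(t, events, init)
    tol = 1e-9
    rises = [ev_t for ev_t, d in events if d > 0]
    qualifying = [
        (t_from, t_to)
        for (t_from, t_to) in runs
        if (t_to - t_from) >= cfg.min_seated_s - tol and t_to in rises
    ]
    if not qualifying:
        raise SegmentationError(
            "no seated start detected",
            f"no seated run of >= {cfg.min_seated_s} s followed by a rise",
        )
    # Prefer the seated run whose rise actually walks away: the last
    # qualifying run ending before the first sit/walk boundary crossing.
    b1_events, _ = _schmitt_events(
        t, x, cfg.sit_walk_boundary_m, cfg.hysteresis_m, refine=refine
    )
    b1_up = [ev_t for ev_t, d in b1_events if d > 0]
    if b1_up:
        before = [r for r in qualifying if r[1] <= b1_up[0] + tol]
        if before:
            return float(before[-1][1])
    return float(qualifying[0][1])


def detect_end(
    signal: DistanceSignal,
    config: BandConfig = BandConfig(),
    after_s: float | None = None,
) -> tuple[float, bool]:
    """Time at which the test ends (participant seated again), in seconds.

    Symmetric with :func:`detect_start`: the end is the interpolated downward
    crossing of ``start_threshold_m`` that begins a seated run lasting at
    least ``min_seated_s`` (or extending to the end of the recording).  If the
    signal never settles below the threshold after ``after_s`` the recording
    is flagged truncated and the last sample time is returned.

    Returns
    -------
    (end_time_s, truncated)
    """
    t, x = signal.time_s, signal.distance_m
    cfg = config
    t0 = t[0] if after_s is None else after_s
    refine = _noise_scale(x) > _REFINE_NOISE_M
    events, init = _schmitt_events(
        t, x, cfg.start_threshold_m, cfg.hysteresis_m, below_at_level=True, refine=refine
    )
    runs = _below_runs(t, events, init)
    tol = 1e-9
    for t_from, t_to in runs:
        if t_from < t0 - tol:
            continue
        span = t_to - t_from
        reaches_end = t_to >= t[-1] - tol
        if span >= cfg.min_seated_s - tol or reaches_end:
            return float(t_from), False
    return float(t[-1]), True


def segment(signal: DistanceSignal, config: BandConfig = BandConfig()) -> SubtaskTimes:
    """Decompose a preprocessed TUG recording into the five subtask times.

    Boundary semantics (all crossings linearly interpolated, with hysteresis):

    * sit-up:       test start -> first upward crossing of the sit/walk boundary
    * walk-forward: -> first upward crossing of the walk/turn boundary
    * turnaround:   time spent at or above the walk/turn boundary
    * walk-back:    last downward crossing of the walk/turn boundary -> downward
      crossing of the sit/walk boundary
    * sit-down:     -> test end (seated below the start threshold again)

    Raises
    ------
    SegmentationError
        ``"incomplete test"`` if the trajectory never reaches the turn band;
        ``"ambiguous trajectory"`` if it enters the turn band more than once.
    """
    t, x = signal.time_s, signal.distance_m
    cfg = config
    start = detect_start(signal, cfg)
    flags: list[str] = []

    b1 = cfg.sit_walk_boundary_m
    b2 = cfg.walk_turn_boundary_m
    refine = _noise_scale(x) > _REFINE_NOISE_M
    b1_events, _ = _schmitt_events(t, x, b1, cfg.hysteresis_m, refine=refine)
    b2_events, _ = _schmitt_events(t, x, b2, cfg.hysteresis_m, refine=refine)
    b1_events = [(et, d) for (et, d) in b1_events if et >= start]
    b2_events = [(et, d) for (et, d) in b2_events if et >= start]

    b2_up = [et for et, d in b2_events if d > 0]
    b2_down = [et for et, d in b2_events if d < 0]
    if len(b2_up) == 0:
        raise SegmentationError("incomplete test", "trajectory never reaches the turn band")
    if len(b2_up) > 1:
        raise SegmentationError(
            "ambiguous trajectory",
            f"{len(b2_up)} separate excursions into the turn band",
        )
    c2_up = b2_up[0]
    if not b2_down:
        raise SegmentationError("incomplete test", "recording ends inside the turn band")
    c2_down = b2_down[-1]

    b1_up = [et for et, d in b1_events if d > 0 and et <= c2_up]
    if not b1_up:
        raise SegmentationError("incomplete test", "no sit/walk boundary crossing before the turn")
    c1 = b1_up[0]

    b1_down = [et for et, d in b1_events if d < 0 and et >= c2_down]
    if b1_down:
        c3 = b1_down[0]
        end, truncated = detect_end(signal, cfg, after_s=c3)
    else:
        c3 = float(t[-1])
        end, truncated = c3, True
    if truncated:
        flags.append("truncated")

    boundaries = {
        "start": start,
        "sit_to_walk": c1,
        "walk_to_turn": c2_up,
        "turn_to_walk": c2_down,
        "walk_to_sit": c3,
        "end": end,
    }
    return SubtaskTimes(
        sit_up_s=c1 - start,
        walk_forward_s=c2_up - c1,
        turn_s=c2_down - c2_up,
        walk_back_s=c3 - c2_down,
        sit_down_s=end - c3,
        total_s=end - start,
        boundary_times_s=boundaries,
        flags=flags,
        meta=dict(signal.meta),
    )


def analyze_tug(signal: DistanceSignal, config: BandConfig = BandConfig()) -> SubtaskTimes:
    """Convenience wrapper: :func:`preprocess` then :func:`segment`."""
    return segment(preprocess(signal, config), config)
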