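"""Tensiomyography (TMG) twitch-parameter extraction.

A TMG trace is the radial displacement of a muscle belly following a single
1 ms supramaximal electrical stimulus at t = 0, sampled at >= 1 kHz.  Three
contractile parameters summarise the twitch:

* ``D_m`` — maximal displacement amplitude (mm), inversely related to muscle
  stiffness;
* ``T_d`` — delay time (ms), stimulus to the first crossing of 10 % of D_m;
* ``T_c`` — contraction time (ms), between the first crossings of 10 % and
  90 % of D_m on the rising phase.

Threshold crossings are located by linear interpolation between the
straddling samples.  Duplicate responses recorded from the same muscle are
combined by averaging the estimated parameters, not the traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["TMGResponse", "TMGParams", "MUSCLES", "extract_params", "average_responses"]

#: The four lower-limb muscles measured: biceps femoris, gastrocnemius
#: medialis, vastus lateralis, vastus medialis.
MUSCLES = ("BF", "GM", "VL", "VM")

#: Parameter keys in canonical order.
TMG_PARAMETERS = ("Tc", "Td", "Dm")


@dataclass
class TMGResponse:
    """One displacement-vs-time twitch trace following a stimulus at t = 0.

    ``time_ms`` must be strictly increasing; samples at t <= 0 (pre-stimulus)
    are allowed and are used for baseline estimation.
    """

    time_ms: np.ndarray
    displacement_mm: np.ndarray
    muscle: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.displacement_mm.shape:
            raise ValueError("time_ms and displacement_mm must be 1-D arrays of equal length")
        if self.time_ms.size < 3:
            raise ValueError("a twitch trace needs at least 3 samples")
        if not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class TMGParams:
    """Contractile parameters of one muscle: (T_c, T_d, D_m)."""

    T_c_ms: float
    T_d_ms: float
    D_m_mm: float
    muscle: str = ""
    n_averaged: int = 1
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "Tc_ms": self.T_c_ms,
            "Td_ms": self.T_d_ms,
            "Dm_mm": self.D_m_mm,
            "n_averaged": self.n_averaged,
        }


class ExtractionError(ValueError):
    """A twitch trace from which no valid parameter set can be extracted."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(f"{reason}: {message}" if message else reason)


def _first_up_crossing(
    t: np.ndarray, y: np.ndarray, level: float, i_start: int, i_stop: int
) -> float:
    """Time of the first upward crossing of ``level`` within [i_start, i_stop].

    Only post-stimulus samples are searched (T_d is defined from the stimulus
    at t = 0).  Linear interpolation between the straddling samples; a
    crossing landing marginally before t = 0 is clamped to 0.  Raises if no
    crossing exists in the window.
    """
    j0 = max(i_start - 1, 0)
    seg = y[j0 : i_stop + 1]
    below = seg[:-1] < level
    atabove = seg[1:] >= level
    idx = np.flatnonzero(below & atabove)
    if idx.size == 0:
        raise ExtractionError(
            "numerical degeneracy", f"level {level:.4g} never crossed before the maximum"
        )
    j = j0 + int(idx[0])
    tc = float(t[j] + (level - y[j]) / (y[j + 1] - y[j]) * (t[j + 1] - t[j]))
    return max(tc, 0.0)


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD estimate from first differences (MAD-based, trend-insensitive)."""
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _quad_crossing(
    t: np.ndarray,
    y: np.ndarray,
    level: float,
    tc0: float,
    lo_bound: int,
    hi_bound: int,
    half: int = 10,
) -> float:
    """Crossing refined by a local quadratic fit (noisy traces only).

    The first noise-assisted crossing of a threshold is early-biased; a
    least-squares parabola through the samples around the straddle follows
    the curvature of the rise and removes both the bias and most of the
    noise.  ``lo_bound`` keeps the window above the onset kink.  Falls back
    to the initial estimate when the fit has no root in the window.
    """
    j = int(np.searchsorted(t, tc0))
    lo = max(lo_bound, j - half)
    hi = min(hi_bound + 1, j + half)
    if hi - lo < 5:
        return tc0
    coef = np.polyfit(t[lo:hi], y[lo:hi], 2)
    coef = coef.copy()
    coef[2] -= level
    roots = np.roots(coef)
    roots = roots[np.isreal(roots)].real
    roots = roots[(roots >= t[lo]) & (roots <= t[hi - 1])]
    if roots.size == 0:
        return tc0
    return float(roots[np.argmin(np.abs(roots - tc0))])


def _peak_amplitude(y: np.ndarray, i_max: int, noisy: bool, half: int = 15) -> float:
    """Response amplitude; a quadratic peak fit avoids the max-of-noise bias."""
    if not noisy:
        return float(y[i_max])
    lo = max(0, i_max - half)
    hi = min(y.size, i_max + half + 1)
    if hi - lo < 5:
        return float(y[i_max])
    idx = np.arange(lo, hi, dtype=float)
    a, b, c = np.polyfit(idx, y[lo:hi], 2)
    if a >= 0:  # not concave at the peak; keep the sample max
        return float(y[i_max])
    x_peak = np.clip(-b / (2 * a), lo, hi - 1)
    return float(np.polyval([a, b, c], x_peak))


def extract_params(response: TMGResponse) -> TMGParams:
    """Extract (T_c, T_d, D_m) from a single twitch trace.

    The baseline is the mean displacement over the pre-stimulus samples
    (t <= 0) when present, else the first sample; it is subtracted before
    thresholding.  When the estimated trace noise exceeds 0.2 % of the
    response amplitude, a 3-sample running median is applied and the
    amplitude and threshold crossings are refined by local polynomial fits
    (see :func:`_quad_crossing` and :func:`_peak_amplitude`).

    Raises
    ------
    ExtractionError
        ``"no contraction detected"`` for a non-positive response amplitude;
        ``"numerical degeneracy"`` when a threshold is never crossed on the
        rising phase.
    """
    t = response.time_ms
    y = response.displacement_mm.astype(float)
    pre = t <= 0.0
    baseline = float(y[pre].mean()) if pre.any() else float(y[0])
    y = y - baseline

    amp0 = float(y.max())
    noisy = amp0 > 0 and _robust_noise_sd(y) > 0.002 * amp0
    if noisy:
        y = ndimage.median_filter(y, size=3, mode="nearest")

    i_zero = int(np.searchsorted(t, 0.0))
    i_max = i_zero + int(np.argmax(y[i_zero:]))
    if float(y[i_max]) <= 0:
        raise ExtractionError("no contraction detected", "response amplitude is not positive")
    if i_max == y.size - 1:
        raise ExtractionError(
            "numerical degeneracy", "maximum at the final sample; trace too short"
        )
    d_m = _peak_amplitude(y, i_max, noisy)
    if d_m <= 0:
        raise ExtractionError("no contraction detected", "response amplitude is not positive")

    t10 = _first_up_crossing(t, y, 0.10 * d_m, i_zero, i_max)
    t90 = _first_up_crossing(t, y, 0.90 * d_m, i_zero, i_max)
    if noisy:
        # keep the fit window above the onset kink, where the trace is flat
        above = np.flatnonzero(y[i_zero:i_max] >= 0.03 * d_m)
        lo_bound = i_zero + (int(above[0]) if above.size else 0)
        t10 = max(_quad_crossing(t, y, 0.10 * d_m, t10, lo_bound, i_max), 0.0)
        t90 = _quad_crossing(t, y, 0.90 * d_m, t90, i_zero, i_max)
        if t90 < t10:
            t90 = t10
    return TMGParams(
        T_c_ms=t90 - t10,
        T_d_ms=t10,
        D_m_mm=d_m,
        muscle=response.muscle,
        n_averaged=1,
        meta=dict(response.meta),
    )


def average_responses(responses: Sequence[TMGResponse]) -> TMGParams:
    """Average the estimated parameters of duplicate responses from one muscle.

    Parameters are extracted per response and arithmetically averaged
    (parameter-level averaging, not trace averaging).  All responses must
    carry the same muscle label.
    """
    if len(responses) == 0:
        raise ValueError("need at least one response")
    muscles = {r.muscle for r in responses}
    if len(muscles) > 1:
        raise ValueError(f"mixed muscle labels: {sorted(muscles)}")
    params = [extract_params(r) for r in responses]
    return TMGParams(
        T_c_ms=float(np.mean([p.T_c_ms for p in params])),
        T_d_ms=float(np.mean([p.T_d_ms for p in params])),
        D_m_mm=float(np.mean([p.D_m_mm for p in params])),
        muscle=responses[0].muscle,
        n_averaged=len(params),
        meta=dict(responses[0].meta),
    )
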