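"""Synthetic TUG distance signals and TMG twitch traces with known ground truth.

The study's clinical recordings were never deposited, so this module emulates
both signal types at the population values the study reports, with exact
ground truth stored alongside every generated recording:

* :func:`generate_tug_signal` builds a distance-from-sensor trajectory whose
  time spent in each distance band equals the requested subtask durations,
  then degrades it with Gaussian noise, 3 cm quantization, and dropouts.
* :func:`generate_twitch` builds a delayed difference-of-exponentials twitch
  whose analytically exact (D_m, T_d, T_c) are computed on a dense grid.
* :func:`generate_cohort` draws whole cohorts in which chosen
  (muscle-parameter, subtask) pairs carry a prescribed population Spearman
  correlation, injected through a Gaussian copula on participant-level latent
  scores, and renders every participant's raw signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

from .tmg import MUSCLES, TMG_PARAMETERS, TMGParams, TMGResponse
from .tug import SUBTASKS, DistanceSignal

__all__ = [
    "TugProfile",
    "NoiseModel",
    "TwitchTruth",
    "CohortSpec",
    "SyntheticTug",
    "SyntheticTwitch",
    "Cohort",
    "generate_tug_signal",
    "generate_twitch",
    "twitch_oracle",
    "twitch_truth_for_params",
    "generate_cohort",
    "TMG_MOMENTS",
    "TUG_MOMENTS",
]

# ---------------------------------------------------------------------------
# population values (mean, SD) from the study cohort of 23 nursing-home
# residents; these are the generator defaults
# ---------------------------------------------------------------------------

#: Per-muscle (mean, SD) of the contractile parameters: Tc, Td in ms, Dm in mm.
TMG_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "BF": {"Tc": (40.79, 8.79), "Td": (30.43, 5.09), "Dm": (4.43, 2.62)},
    "GM": {"Tc": (31.60, 6.67), "Td": (25.82, 3.72), "Dm": (2.49, 1.33)},
    "VL": {"Tc": (29.94, 8.07), "Td": (28.08, 3.50), "Dm": (3.74, 1.68)},
    "VM": {"Tc": (47.22, 12.16), "Td": (29.07, 3.33), "Dm": (5.84, 2.42)},
}

#: (mean, SD) of the five subtask durations in seconds.
TUG_MOMENTS: dict[str, tuple[float, float]] = {
    "sit_up": (4.51, 2.12),
    "walk_forward": (3.78, 1.46),
    "turn": (3.00, 2.00),
    "walk_back": (4.41, 2.58),
    "sit_down": (4.59, 2.34),
}

#: Physiological lower truncation bounds for drawn TMG parameters.
TMG_LOWER_BOUNDS = {"Tc": 10.0, "Td": 16.0, "Dm": 0.3}

_START_THRESHOLD_M = 0.10
_SIT_WALK_BOUNDARY_M = 0.995
_WALK_TURN_BOUNDARY_M = 3.195
_LEAN_S = 0.2  # brief torso transition between the seated distance and 0.10 m
_SIT_MID_M = 0.30  # trunk-transit waypoint inside the sit band


# ---------------------------------------------------------------------------
# TUG distance signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TugProfile:
    """Ground-truth subtask durations and geometry of one synthetic TUG test."""

    sit_up_s: float = 4.51
    walk_forward_s: float = 3.78
    turn_s: float = 3.00
    walk_back_s: float = 4.41
    sit_down_s: float = 4.59
    seated_distance_m: float = 0.05
    turn_apex_m: float = 3.35

    def __post_init__(self):
        for name in ("sit_up_s", "walk_forward_s", "turn_s", "walk_back_s", "sit_down_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite duration, got {v!r}")
        if not (0 < self.seated_distance_m < _START_THRESHOLD_M):
            raise ValueError("seated_distance_m must lie below the 0.10 m start threshold")
        if not (3.20 <= self.turn_apex_m <= 3.50):
            raise ValueError("turn_apex_m must lie within the turn band [3.20, 3.50] m")

    def durations(self) -> dict[str, float]:
        return {
            "sit_up": self.sit_up_s,
            "walk_forward": self.walk_forward_s,
            "turn": self.turn_s,
            "walk_back": self.walk_back_s,
            "sit_down": self.sit_down_s,
        }


@dataclass(frozen=True)
class NoiseModel:
    """Sensor degradation: additive Gaussian noise, then quantization, then dropouts.

    The 3 cm default quantization models the device's stated accuracy;
    dropouts become NaN readings.
    """

    quantization_m: float = 0.03
    gaussian_sd_m: float = 0.0
    dropout_prob: float = 0.0
    seed: object = None

    def __post_init__(self):
        if self.quantization_m < 0 or self.gaussian_sd_m < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(quantization_m=0.0, gaussian_sd_m=0.0, dropout_prob=0.0)


@dataclass
class SyntheticTug:
    """A generated TUG recording with its ground truth."""

    signal: DistanceSignal
    #: boundary times on the recording's time axis plus the true durations
    truth: dict
    profile: TugProfile
    #: noiseless distance trace on the same time grid
    clean_m: np.ndarray


def _tug_segments(profile: TugProfile, lead_in_s: float, lead_out_s: float):
    """Piecewise trajectory as (t0, t1, fn(local s in [0,1])) plus truth times.

    Sit phases are two-piece linear inside the sit band (quick trunk transit
    near the chair, then the slower progression); walking phases are
    constant-velocity between the band boundaries; the turnaround uses cosine
    ramps into a flat dwell at the apex, so the slope is zero only at the
    apex, away from every detection boundary.
    """
    seated = profile.seated_distance_m
    thr, b_sit, b_turn = _START_THRESHOLD_M, _SIT_WALK_BOUNDARY_M, _WALK_TURN_BOUNDARY_M
    apex = profile.turn_apex_m
    r = min(0.6, profile.turn_s / 4.0)  # turn ramp duration
    dwell = profile.turn_s - 2.0 * r
    # Sit phases are two-piece linear: the trunk transit near the chair
    # (0.10 -> 0.30 m) is quick even in slow performers; slow overall sit
    # times come from the later progression through the band.
    rise_fast = min(1.0, 0.25 * profile.sit_up_s)
    fall_fast = min(1.0, 0.25 * profile.sit_down_s)

    t0 = lead_in_s
    t_start = t0 + _LEAN_S
    t1 = t_start + profile.sit_up_s
    t2 = t1 + profile.walk_forward_s
    t3 = t2 + profile.turn_s
    t4 = t3 + profile.walk_back_s
    t5 = t4 + profile.sit_down_s
    t_lean_back = t5 + _LEAN_S
    t_total = t_lean_back + lead_out_s

    segs = [
        (0.0, t0, lambda s: np.full_like(s, seated)),
        (t0, t_start, lambda s: seated + (thr - seated) * s),
        (t_start, t_start + rise_fast, lambda s: thr + (_SIT_MID_M - thr) * s),
        (t_start + rise_fast, t1, lambda s: _SIT_MID_M + (b_sit - _SIT_MID_M) * s),
        (t1, t2, lambda s: b_sit + (b_turn - b_sit) * s),
        (t2, t2 + r, lambda s: b_turn + (apex - b_turn) * np.sin(0.5 * np.pi * s)),
        (t2 + r, t2 + r + dwell, lambda s: np.full_like(s, apex)),
        (t3 - r, t3, lambda s: b_turn + (apex - b_turn) * np.cos(0.5 * np.pi * s)),
        (t3, t4, lambda s: b_turn + (b_sit - b_turn) * s),
        (t4, t5 - fall_fast, lambda s: b_sit + (_SIT_MID_M - b_sit) * s),
        (t5 - fall_fast, t5, lambda s: _SIT_MID_M + (thr - _SIT_MID_M) * s),
        (t5, t_lean_back, lambda s: thr + (seated - thr) * s),
        (t_lean_back, t_total, lambda s: np.full_like(s, seated)),
    ]
    truth = {
        "start": t_start,
        "sit_to_walk": t1,
        "walk_to_turn": t2,
        "turn_to_walk": t3,
        "walk_to_sit": t4,
        "end": t5,
        "sit_up_s": profile.sit_up_s,
        "walk_forward_s": profile.walk_forward_s,
        "turn_s": profile.turn_s,
        "walk_back_s": profile.walk_back_s,
        "sit_down_s": profile.sit_down_s,
        "total_s": t5 - t_start,
    }
    return segs, truth, t_total


def _eval_trajectory(segs, t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    out[:] = np.nan
    for t0, t1, fn in segs:
        if t1 <= t0:
            continue
        mask = (t >= t0) & (t < t1)
        if mask.any():
            out[mask] = fn((t[mask] - t0) / (t1 - t0))
    # samples at/after the final knot hold the final seated level
    tail = t >= segs[-1][1]
    if tail.any():
        out[tail] = segs[-1][2](np.ones(tail.sum()))
    return out


def generate_tug_signal(
    profile: TugProfile,
    noise: NoiseModel | None = None,
    sample_rate_hz: float = 10.0,
    lead_in_s: float = 2.0,
    lead_out_s: float = 2.0,
    meta: dict | None = None,
) -> SyntheticTug:
    """Render one TUG recording at the given sample rate.

    The noiseless trajectory is piecewise monotone: seated below the start
    threshold for ``lead_in_s``, rising through the sit and walk bands in
    exactly ``sit_up_s`` and ``walk_forward_s``, at or above the walk/turn
    boundary for exactly ``turn_s``, then descending symmetrically.  Ground
    truth boundary times are returned alongside the (optionally degraded)
    signal.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    dt = 1.0 / sample_rate_hz
    for name, v in profile.durations().items():
        if v < dt:
            raise ValueError(
                f"profile duration {name}={v:.3g} s is shorter than one sample period ({dt:.3g} s)"
            )
    if lead_in_s < 1.0 or lead_out_s < 1.0:
        raise ValueError("lead_in_s and lead_out_s must be at least 1 s (seated dwell)")

    segs, truth, t_total = _tug_segments(profile, lead_in_s, lead_out_s)
    n = int(math.floor(t_total * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    clean = _eval_trajectory(segs, t)

    x = clean.copy()
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.gaussian_sd_m > 0:
            x = x + rng.normal(0.0, noise.gaussian_sd_m, size=x.shape)
        if noise.quantization_m > 0:
            x = np.round(x / noise.quantization_m) * noise.quantization_m
        x = np.clip(x, 0.0, 6.0)
        if noise.dropout_prob > 0:
            x[rng.random(x.shape) < noise.dropout_prob] = np.nan

    sig = DistanceSignal(time_s=t, distance_m=x, meta=dict(meta or {}))
    return SyntheticTug(signal=sig, truth=truth, profile=profile, clean_m=clean)


# ---------------------------------------------------------------------------
# TMG twitch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchTruth:
    """Parameters of a delayed difference-of-exponentials twitch.

    d(t) = A * c * (exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise)) for t >= t0,
    zero before, with c chosen so the maximum equals ``amplitude_mm``.
    ``decay_tau_ms > rise_tau_ms`` guarantees a unique interior maximum.
    """

    amplitude_mm: float
    latency_ms: float = 10.0
    rise_tau_ms: float = 20.0
    decay_tau_ms: float = 200.0
    sample_rate_hz: float = 1000.0
    noise_sd_mm: float = 0.0
    seed: object = None

    def __post_init__(self):
        vals = (self.amplitude_mm, self.latency_ms, self.rise_tau_ms, self.decay_tau_ms)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("twitch parameters must be finite")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be non-negative")
        if self.rise_tau_ms <= 0:
            raise ValueError("rise_tau_ms must be positive")
        if self.decay_tau_ms <= self.rise_tau_ms:
            raise ValueError("decay_tau_ms must exceed rise_tau_ms")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")


@dataclass
class SyntheticTwitch:
    """A generated twitch trace with its dense-grid oracle parameters."""

    response: TMGResponse
    oracle: TMGParams | None
    truth: TwitchTruth


def _peak_time_rel(rise_tau: float, decay_tau: float) -> float:
    """Time of the twitch maximum after onset, analytically."""
    return rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)


def _unit_twitch(x: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Normalized (unit-peak) twitch shape at times ``x`` after onset."""
    tp = _peak_time_rel(rise_tau, decay_tau)
    peak = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    xp = x[pos]
    out[pos] = (np.exp(-xp / decay_tau) - np.exp(-xp / rise_tau)) / peak
    return out


def twitch_oracle(truth: TwitchTruth, oversample: int = 100) -> TMGParams:
    """Exact (D_m, T_d, T_c) of the noiseless curve by dense-grid crossing search.

    The grid spacing is ``oversample`` times finer than the trace's sampling
    interval (at least 100x).  D_m equals the target amplitude by the
    normalization of the parametric form.
    """
    oversample = max(int(oversample), 100)
    step = 1000.0 / truth.sample_rate_hz / oversample
    tp = _peak_time_rel(truth.rise_tau_ms, truth.decay_tau_ms)
    x = np.arange(0.0, tp + step, step)
    y = _unit_twitch(x, truth.rise_tau_ms, truth.decay_tau_ms)

    def crossing(level: float) -> float:
        i = int(np.argmax(y >= level))
        if i == 0:
            return 0.0
        return float(x[i - 1] + (level - y[i - 1]) / (y[i] - y[i - 1]) * (x[i] - x[i - 1]))

    t10 = crossing(0.10)
    t90 = crossing(0.90)
    return TMGParams(
        T_c_ms=t90 - t10,
        T_d_ms=truth.latency_ms + t10,
        D_m_mm=truth.amplitude_mm,
        muscle="",
        n_averaged=1,
    )


def generate_twitch(
    truth: TwitchTruth,
    pre_stimulus_ms: float = 10.0,
    oracle: bool = True,
    muscle: str = "",
    meta: dict | None = None,
) -> SyntheticTwitch:
    """Render a twitch trace sampled at ``truth.sample_rate_hz``.

    The trace spans ``pre_stimulus_ms`` before the stimulus through six decay
    time constants after onset, so the full rise and most of the relaxation
    are contained.  Gaussian measurement noise of SD ``truth.noise_sd_mm`` is
    added when non-zero.  With ``oracle=True`` the dense-grid exact
    parameters of the noiseless curve are returned alongside.
    """
    step = 1000.0 / truth.sample_rate_hz
    dur = truth.latency_ms + 6.0 * truth.decay_tau_ms
    t = np.arange(-pre_stimulus_ms, dur + 0.5 * step, step)
    y = truth.amplitude_mm * _unit_twitch(t - truth.latency_ms, truth.rise_tau_ms, truth.decay_tau_ms)
    if truth.noise_sd_mm > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd_mm, size=y.shape)
    resp = TMGResponse(time_ms=t, displacement_mm=y, muscle=muscle, meta=dict(meta or {}))
    orc = twitch_oracle(truth) if oracle else None
    if orc is not None:
        orc.muscle = muscle
    return SyntheticTwitch(response=resp, oracle=orc, truth=truth)


# --- inversion: from target (D_m, T_d, T_c) back to curve parameters -------

def _rise_crossings_analytic(rise_tau: float, decay_tau: float) -> tuple[float, float]:
    """(t10, t90) after onset of the unit twitch, by root finding."""
    tp = _peak_time_rel(rise_tau, decay_tau)

    def f(x: float, level: float) -> float:
        return float(_unit_twitch(np.array([x]), rise_tau, decay_tau)[0]) - level

    t10 = brentq(f, 1e-12, tp, args=(0.10,), xtol=1e-10)
    t90 = brentq(f, t10, tp, args=(0.90,), xtol=1e-10)
    return t10, t90


@lru_cache(maxsize=8)
def _tc_table(decay_tau: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monotone lookup table rise_tau -> (T_c, t10) for a fixed decay tau."""
    taus = np.geomspace(0.02, 0.98 * decay_tau, 400)
    t10s = np.empty_like(taus)
    tcs = np.empty_like(taus)
    for i, tr in enumerate(taus):
        t10, t90 = _rise_crossings_analytic(float(tr), decay_tau)
        t10s[i], tcs[i] = t10, t90 - t10
    if not np.all(np.diff(tcs) > 0):
        raise RuntimeError("contraction time is not monotone in rise tau")  # pragma: no cover
    return taus, tcs, t10s


def twitch_truth_for_params(
    dm_mm: float,
    td_ms: float,
    tc_ms: float,
    decay_tau_ms: float = 150.0,
    sample_rate_hz: float = 1000.0,
    noise_sd_mm: float = 0.0,
    seed: object = None,
) -> TwitchTruth:
    """Curve parameters whose noiseless twitch has the requested (D_m, T_d, T_c).

    The decay time constant is fixed (it does not affect the three extracted
    parameters' targets); the rise time constant is solved from T_c and the
    onset latency from T_d.  A T_d smaller than the curve's own 10 % rise lag
    is clamped to zero latency (the realized T_d then slightly exceeds the
    target).
    """
    taus, tcs, t10s = _tc_table(float(decay_tau_ms))
    if not (tcs[0] <= tc_ms <= tcs[-1]):
        raise ValueError(
            f"T_c={tc_ms:.3g} ms outside the achievable range "
            f"[{tcs[0]:.3g}, {tcs[-1]:.3g}] for decay_tau={decay_tau_ms:.3g} ms"
        )
    i = int(np.searchsorted(tcs, tc_ms))
    lo, hi = taus[max(i - 1, 0)], taus[min(i, taus.size - 1)]
    if lo == hi:
        rise_tau = float(lo)
    else:
        rise_tau = brentq(
            lambda tr: _rise_crossings_analytic(tr, decay_tau_ms)[1]
            - _rise_crossings_analytic(tr, decay_tau_ms)[0]
            - tc_ms,
            lo,
            hi,
            xtol=1e-9,
        )
    t10, _ = _rise_crossings_analytic(float(rise_tau), float(decay_tau_ms))
    latency = max(0.0, td_ms - t10)
    return TwitchTruth(
        amplitude_mm=dm_mm,
        latency_ms=latency,
        rise_tau_ms=float(rise_tau),
        decay_tau_ms=float(decay_tau_ms),
        sample_rate_hz=sample_rate_hz,
        noise_sd_mm=noise_sd_mm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# whole-cohort synthesis with injected correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-scale synthetic cohort description.

    ``target_correlations`` lists ((muscle, parameter), subtask, rho) triples;
    the population Spearman correlation between the named participant-level
    muscle parameter and subtask duration is injected through a Gaussian
    copula (rank correlation converted to the latent Pearson correlation by
    r = 2 sin(pi * rho / 6)); all unlisted pairs are independent.
    """

    n_participants: int = 23
    tests_per_participant: int = 6
    tmg_replicates: int = 2
    tmg_moments: dict = field(default_factory=lambda: {m: dict(v) for m, v in TMG_MOMENTS.items()})
    tug_moments: dict = field(default_factory=lambda: dict(TUG_MOMENTS))
    target_correlations: list = field(default_factory=list)
    seed: object = None
    sample_rate_hz: float = 10.0
    tmg_sample_rate_hz: float = 1000.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(gaussian_sd_m=0.03))
    tmg_noise_sd_mm: float = 0.01
    #: test-to-test SD of each subtask duration within a participant, seconds
    within_subtask_sd_s: float = 0.3
    #: lower truncation of drawn subtask durations, seconds
    min_duration_s: float = 1.0
    decay_tau_ms: float = 200.0

    def __post_init__(self):
        if self.n_participants < 3:
            raise ValueError("n_participants must be at least 3")
        if self.tests_per_participant < 1 or self.tmg_replicates < 1:
            raise ValueError("counts must be positive")
        for (muscle, param), subtask, rho in self.target_correlations:
            if muscle not in self.tmg_moments or param not in self.tmg_moments[muscle]:
                raise ValueError(f"unknown muscle parameter ({muscle}, {param})")
            if subtask not in self.tug_moments:
                raise ValueError(f"unknown subtask {subtask!r}")
            if not abs(rho) <= 1:
                raise ValueError(f"|rho| must be <= 1, got {rho}")


@dataclass
class Cohort:
    """A synthetic study dataset: raw recordings plus stored ground truth."""

    spec: CohortSpec
    #: list of dicts: participant_id, test_index, recording (SyntheticTug)
    tug_recordings: list
    #: list of dicts: participant_id, muscle, replicate, recording (SyntheticTwitch)
    tmg_recordings: list
    #: participant-level true subtask durations (one row per participant)
    truth_tug: pd.DataFrame
    #: participant-level true contractile parameters (row per participant x muscle)
    truth_tmg: pd.DataFrame

    @property
    def participant_ids(self) -> list:
        return list(self.truth_tug["participant_id"])


def _copula_matrix(spec: CohortSpec, variables: list) -> np.ndarray:
    r = np.eye(len(variables))
    index = {v: i for i, v in enumerate(variables)}
    for (muscle, param), subtask, rho in spec.target_correlations:
        i, j = index[(muscle, param)], index[("tug", subtask)]
        r_latent = 2.0 * math.sin(math.pi * rho / 6.0)
        r[i, j] = r[j, i] = r_latent
    return r


def generate_cohort(spec: CohortSpec, render_signals: bool = True) -> Cohort:
    """Draw a full synthetic cohort and render all raw signals.

    With ``render_signals=False`` only the participant-level ground truth is
    drawn (useful for studying the injected correlation structure itself);
    the recording lists are then empty.

    Participant-level muscle parameters and subtask durations are mapped from
    the copula's latent Gaussian scores through truncated-normal inverse CDFs
    at the population moments (a strictly monotone map, so the injected
    Spearman targets transfer exactly in population).  Each participant then
    receives ``tests_per_participant`` TUG recordings (durations jittered
    test-to-test) and ``tmg_replicates`` twitch traces per muscle.

    Raises
    ------
    ValueError
        if the implied latent correlation matrix is not positive definite
        (infeasible correlation targets).
    """
    variables = [(m, p) for m in MUSCLES for p in TMG_PARAMETERS]
    variables += [("tug", s) for s in SUBTASKS]
    r = _copula_matrix(spec, variables)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "infeasible correlation targets: the implied latent correlation "
            "matrix is not positive definite"
        ) from None

    ss = np.random.SeedSequence(spec.seed) if spec.seed is not None else np.random.SeedSequence()
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = spec.n_participants

    z = rng.standard_normal((n, len(variables))) @ chol.T
    u = ndtr(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)

    values: dict = {}
    for k, var in enumerate(variables):
        if var[0] == "tug":
            mean, sd = spec.tug_moments[var[1]]
            lb = spec.min_duration_s
        else:
            mean, sd = spec.tmg_moments[var[0]][var[1]]
            lb = TMG_LOWER_BOUNDS[var[1]]
        a = (lb - mean) / sd
        # draws truncated at +/-4 SD (upper) to stay physiological
        b = max(a + 1e-6, 4.0)
        values[var] = truncnorm.ppf(u[:, k], a, b, loc=mean, scale=sd)

    pids = [f"P{i + 1:02d}" for i in range(n)]
    truth_tug = pd.DataFrame({"participant_id": pids})
    for s in SUBTASKS:
        truth_tug[f"{s}_s"] = values[("tug", s)]
    truth_tug["total_s"] = sum(values[("tug", s)] for s in SUBTASKS)

    truth_tmg = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "muscle": m,
                "Tc_ms": values[(m, "Tc")][i],
                "Td_ms": values[(m, "Td")][i],
                "Dm_mm": values[(m, "Dm")][i],
            }
            for i, pid in enumerate(pids)
            for m in MUSCLES
        ]
    )

    if not render_signals:
        return Cohort(spec=spec, tug_recordings=[], tmg_recordings=[],
                      truth_tug=truth_tug, truth_tmg=truth_tmg)

    n_tug = n * spec.tests_per_participant
    n_tmg = n * len(MUSCLES) * spec.tmg_replicates
    noise_seeds = ss.spawn(n_tug + n_tmg + 1)
    jitter_rng = np.random.default_rng(noise_seeds[-1])

    tug_recordings = []
    k = 0
    for i, pid in enumerate(pids):
        for test_idx in range(spec.tests_per_participant):
            durs = {}
            for s in SUBTASKS:
                base = values[("tug", s)][i]
                a = (0.5 - base) / spec.within_subtask_sd_s
                durs[s] = float(
                    truncnorm.ppf(
                        jitter_rng.random(), a, np.inf, loc=base, scale=spec.within_subtask_sd_s
                    )
                )
            profile = TugProfile(
                sit_up_s=durs["sit_up"],
                walk_forward_s=durs["walk_forward"],
                turn_s=durs["turn"],
                walk_back_s=durs["walk_back"],
                sit_down_s=durs["sit_down"],
                seated_distance_m=0.05,
                turn_apex_m=float(jitter_rng.uniform(3.30, 3.45)),
            )
            rec = generate_tug_signal(
                profile,
                noise=replace(spec.noise, seed=noise_seeds[k]),
                sample_rate_hz=spec.sample_rate_hz,
                meta={"participant_id": pid, "test_index": test_idx},
            )
            tug_recordings.append(
                {"participant_id": pid, "test_index": test_idx, "recording": rec}
            )
            k += 1

    tmg_recordings = []
    for i, pid in enumerate(pids):
        for m in MUSCLES:
            truth = twitch_truth_for_params(
                dm_mm=float(values[(m, "Dm")][i]),
                td_ms=float(values[(m, "Td")][i]),
                tc_ms=float(values[(m, "Tc")][i]),
                decay_tau_ms=spec.decay_tau_ms,
                sample_rate_hz=spec.tmg_sample_rate_hz,
                noise_sd_mm=spec.tmg_noise_sd_mm,
            )
            for rep in range(spec.tmg_replicates):
                rec = generate_twitch(
                    replace(truth, seed=noise_seeds[k]),
                    oracle=False,
                    muscle=m,
                    meta={"participant_id": pid, "replicate": rep},
                )
                tmg_recordings.append(
                    {"participant_id": pid, "muscle": m, "replicate": rep, "recording": rec}
                )
                k += 1

    return Cohort(
        spec=spec,
        tug_recordings=tug_recordings,
        tmg_recordings=tmg_recordings,
        truth_tug=truth_tug,
        truth_tmg=truth_tmg,
    )
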