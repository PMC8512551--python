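# Methods

## Problem setting

A chair-mounted ultrasonic sensor records a person's distance from the chair
at a nominal 10 Hz with about 3 cm accuracy while they perform a Timed
Up-and-Go (TUG) test: stand up, walk 3 m, turn, walk back, sit down.  The
distance-over-time trace decomposes the test into five subtasks through fixed
distance bands — sit-up/sit-down between 0 and 0.99 m, walk-forward/walk-back
between 1.00 and 3.19 m, turnaround between 3.20 and 3.50 m — with the seated
start/end criterion "distance < 0.10 m".  Tensiomyography (TMG) separately
characterizes four lower-limb muscles (biceps femoris BF, gastrocnemius
medialis GM, vastus lateralis VL, vastus medialis VM) by three twitch
parameters: maximal radial displacement D_m (mm), delay time T_d (stimulus to
10 % of D_m, ms) and contraction time T_c (10 % to 90 % of D_m, ms).  The
package reimplements the full analysis chain — segmentation, extraction,
participant-level aggregation, Spearman correlation with Bonferroni
adjustment — plus a synthetic-data generator, because no clinical recordings
are publicly available.

## Segmentation

The 1 cm gaps between the printed band edges (0.99/1.00 m and 3.19/3.20 m)
are treated as single boundaries at their midpoints, 0.995 m and 3.195 m: the
bands are contiguous labels, not dead zones.  Crossings are detected by a
Schmitt trigger with a 0.05 m hysteresis margin (one sensor-resolution step
above the 3 cm quantization), so boundary chatter never produces spurious
events.  For the seated threshold the trigger is asymmetric — "below" is the
literal criterion distance < 0.10 m, "above" requires threshold + hysteresis —
because the seated distance itself (typically 4–8 cm) can lie inside a
symmetric hysteresis band.

Crossing *times* are located by linear interpolation between the straddling
samples.  When the recording is measurably noisy (robust second-difference
noise scale above 5 mm), each crossing is instead estimated by two local
least-squares lines, one per side of the straddle, each extrapolated to the
boundary level and combined by inverse-variance weights.  The two-sided form
matters: the trajectory may change slope exactly at a band boundary (walking
speed differs from sit-to-stand speed), so a single straddling fit would be
biased toward the steeper side, while each one-sided fit converges on the
true crossing.  On noiseless data the estimator reduces to plain
interpolation, which matches a dense-grid brute-force crossing search to
1 micro-second (tested).

Preprocessing replaces non-finite and out-of-range readings (outside 0–6 m)
by linear interpolation, rejects recordings with more than 20 % invalid
samples, and applies a 3-sample running median.  Start and end are the
interpolated threshold crossings that terminate/begin a seated run of at
least 1 s; a recording that never settles back below the threshold is
flagged `truncated` rather than rejected.  The five subtask durations
telescope between consecutive boundaries, so they sum to the total exactly.

Known limitation: for very slow performers the distance trace approaches the
seated threshold slowly and the start/end estimate degrades toward
~0.1–0.2 s error under 3 cm noise; this is an information limit of the
10 Hz, 3 cm signal, not of the estimator.

## Twitch model and extraction

The synthetic twitch is a delayed difference of exponentials,
d(t) = A·c·(e^{−(t−t0)/τ_d} − e^{−(t−t0)/τ_r}) for t ≥ t0, with c chosen so
the maximum equals A.  This standard twitch form has a unique interior
maximum and analytically tractable crossings; its exact (D_m, T_d, T_c) are
computed on a grid at least 100x finer than the sampling interval and stored
as oracle values with every generated trace.

Extraction subtracts a baseline (mean over pre-stimulus samples), finds D_m
as the post-stimulus maximum, and locates the first upward crossings of
0.1·D_m and 0.9·D_m by linear interpolation, searching only after the
stimulus.  On noisy traces (noise above 0.2 % of the amplitude) three
refinements remove small-sample bias: a 3-point running median, a local
quadratic fit at the peak (the raw maximum of a noisy trace is upward-biased,
which would inflate the 90 % threshold where the curve is flattest), and
local quadratic fits at the two crossings, windowed to stay above the onset
kink.  Without these the contraction time carries a bias comparable to its
scatter and duplicate-averaging cannot beat a single measurement.

Duplicate responses are combined by averaging the *estimated parameters*,
not the traces, and the count is recorded (`n_averaged`).

## Statistics

Participant records are arithmetic means over that participant's tests and
sessions; participants lacking either modality are excluded and logged.
Spearman's rho is the Pearson correlation of average ranks (ties get average
ranks).  The two-sided p-value uses the exact permutation distribution
(all n! assignments, vectorized) for n ≤ 9 and the t approximation
t = rho·sqrt((n−2)/(1−rho²)) with n−2 degrees of freedom above that; the
cutoff is a convention, chosen so the exact branch stays cheap, and either
method can be forced.  The Bonferroni-adjusted threshold is alpha/k with
k = 12 (the twelve muscle parameters) by default, which reproduces the
printed 0.0042 at alpha = 0.05; k is configurable because "the number of
performed correlations" could also be read as all 72 cells.  Descriptive
statistics pool all measurements by default (the min/max spans in the source
tables indicate test-level granularity); a flag switches to participant
means.  Undefined correlations (zero rank variance) are reported missing,
never imputed.

## Synthetic data generator

The generator's defaults are the study's conditions: 23 participants, up to
6 TUG tests each, two TMG replicates per muscle, 10 Hz distance sampling
with 3 cm Gaussian noise and 3 cm quantization, 1 kHz twitch sampling with
0.01 mm sensor noise, and population moments for all 17 variables (12 muscle
parameters, 5 subtask durations) taken from the published cohort table.

The distance trajectory is piecewise monotone with exactly controllable
band-occupancy times: seated (≥ 1 s, default 2 s) below the threshold, a
0.2 s lean to the threshold, a two-piece linear sit-up (a quick trunk
transit from 0.10 to 0.30 m taking the smaller of 1 s and a quarter of the
sit-up time, then constant velocity to the sit/walk boundary — the slow part
of a slow sit-up is the later progression, not the initial trunk motion),
constant-velocity walking, and a turnaround that ramps into a flat apex
dwell by quarter-cosines (ramp ≤ 0.6 s) so the slope is zero only at the
apex, away from every detection boundary.  Sit-down mirrors sit-up.  Noise
is applied as Gaussian jitter, then rounding to the 3 cm grid, then optional
dropouts (NaN).  Every boundary time is stored as ground truth.

Cohorts are drawn through a Gaussian copula on participant-level latent
scores: requested (muscle-parameter, subtask) Spearman targets are converted
to latent Pearson correlations by r = 2·sin(pi·rho/6); all unlisted pairs are
independent; a non-positive-definite implied matrix is rejected.  Latent
scores map to values by truncated-normal inverse CDFs at the population
moments — a strictly monotone map, so rank correlations transfer exactly.
Truncation bounds (durations ≥ 1 s, T_c ≥ 10 ms, T_d ≥ 16 ms, D_m ≥ 0.3 mm,
all variables ≤ mean + 4 SD) keep every draw renderable: a 10 Hz trace
cannot represent a 0.13 s turnaround, and the twitch shape bounds the
achievable T_c for a given decay constant.  Note the truncation shifts the
realized generating means slightly above the nominal ones (most visibly for
the turnaround, whose nominal SD is large); validation against generated
data must therefore compare to the truncated-normal mean, not the nominal
table value.  Test-to-test variation adds 0.3 s SD jitter per subtask within
a participant.  Drawn (D_m, T_d, T_c) are mapped back to twitch-curve
parameters by fixing the decay constant (200 ms) and numerically inverting
T_c -> rise constant (monotone; solved by bracketed root finding over a
cached lookup table) and T_d -> onset latency.

What the generator does *not* emulate: torso lean-forward transiently
shortening the distance during sit-up (the trace is monotone within each
half), walking aids or second persons in the beam, gait oscillations,
asymmetric or pathological twitch shapes, and any distributional shape
beyond the (truncated) normal margins.  Passing recovery tests therefore
demonstrates correctness of the *algorithms* under the stated noise, not
robustness to every clinical artifact.

## Numerical and design choices

- All randomness flows from one seed per call through spawned NumPy
  `SeedSequence` children; identical configuration and seed reproduce every
  signal and output file byte for byte.
- Crossing and fit windows: hysteresis 0.05 m, two-sided fit 8 samples per
  side, extraction quadratic windows ±10 samples (1 kHz), peak window ±15.
- The exact-permutation branch caps at n = 9 (9! = 362 880 permutations,
  still vectorizable); the study's n = 23 always uses the t approximation.
- Degenerate inputs fail loudly with named reasons ("incomplete test",
  "ambiguous trajectory", "no contraction detected", ...) and per-file
  failures are logged and reported, never silently dropped.
- Problem sizes in the validation suite (100 noisy recordings for
  segmentation recovery, 200 random twitches, 500 permutation instances,
  200 cohorts for correlation recovery, 40 null cohorts) were chosen to give
  Monte-Carlo error comfortably below each pass margin.
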