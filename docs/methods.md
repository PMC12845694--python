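# Methods

This note documents the models, parameters, numerical choices and known
limitations of `respgate`. Everything stated here is computed by the test
suite or the demo/acceptance scripts; nothing is quoted from external
measurements.

## State-space model

Respiratory displacement is modeled as a baseline-offset harmonic
oscillator with state `x = (Xr, Vr, C)`:

* `Xr` [mm] — oscillatory respiratory displacement,
* `Vr` [mm/s] — its velocity,
* `C` [mm] — slowly varying non-respiratory baseline (posture, drift).

The forward-Euler transition at sample interval `dt` is

```
A = [[1, dt, 0], [-w^2 dt, 1, 0], [0, 0, 1]],   w = 2*pi*f_r,
```

whose oscillator block has eigenvalues of magnitude `sqrt(1 + w^2 dt^2)`
— marginally expanding at O((w dt)^2), negligible at 100 Hz and corrected
continuously by measurement updates. The scalar observation is
`z = Xr + C + v` with `v ~ N(0, R)`: the tracker measures displacement
plus bias, never velocity, so the observation row is `[1, 0, 1]` by
physics, not tuning. A single-step state propagation of an exact
oscillator state deviates from the closed-form sine by O(dt^2) per step
(tested).

## Adaptation loops

Three quantities are re-estimated causally while filtering (refreshed every
`adapt_stride` = 10 samples = 0.1 s; respiratory quantities vary on second
timescales, so a 0.1 s refresh is output-indistinguishable from per-sample
refresh at a tenth of the cost):

* **frequency** `f_r`: reciprocal mean peak-to-peak interval of the
  filtered `Xr` over a rolling 20 s buffer. Peaks are prominence-filtered
  (≥ 20% of the buffer range — amplitude-scale-free) with minimum
  separation `1/f_max`. The raw value feeds a one-pole IIR low-pass
  (cutoff 0.05 Hz, per-sample coefficient `a = 1 - exp(-2*pi*0.05*dt)`,
  time constant ≈ 3.2 s) and is clamped to `[f_min, f_max] = [0.05, 1.0]`
  Hz, a generous envelope around the 10–20 breaths/min resting range.
  With fewer than two detectable peaks the previous value is kept.
* **measurement noise** `R = sigma_noise^2`: for i.i.d. noise
  `var(diff(z)) = 2 sigma^2` while the first difference of smooth
  respiration is negligible at 100 Hz, so
  `sigma_noise = sd(diff(z)) / sqrt(2)` over the last 5 s, floored at
  1e-6 mm. Recovered within a few percent of an injected 0.5 mm sd
  (tested at n = 2000).
* **process noise** `Q = diag(q0, w^2, alpha * sigma_resp^2)` with
  `q0 = 1`, `alpha = 0.01` and `sigma_resp^2` the variance of `Xr` over
  the last 60 s. `Q` is interpreted as a continuous-time noise
  *intensity*; the per-step covariance in the recursion is `Q * dt`.
  This is the standard discretization and is load-bearing: applying the
  same numbers per step at 100 Hz makes the filter essentially
  pass-through (innovations acquire MA(1) structure with lag-1
  autocorrelation ≈ −0.5, and the smoothing gain nearly vanishes),
  whereas with `Q * dt` innovations on a matched simulation are
  near-white (lag-1 ≈ −0.15, tested) and the filtered RMSE on a noisy
  sine is roughly half the raw RMSE.

## Initialization

`x0 = (0, 0, z0)`, `P0 = 25 * I`: the first sample is assigned entirely to
the baseline, so the trace is a strictly causal function of the input
prefix (truncating the input and re-running reproduces the prefix exactly
— tested). Because `Vr` is unobservable from a single sample, a
**two-point-differencing warm start** replaces the zero initial velocity
once `init_window_s` = 0.5 s of data has arrived, using the
finite-difference slope between short averages at the window edges. This
is the textbook initialization for position–velocity trackers; without it
velocity convergence takes about one breathing cycle and the first cycle's
prompt is missed.

## Prediction and latency compensation

Point predictions iterate the transition matrix: `x_{k+h|k} = A^h x_k`.
Because the filter tracks the *delayed* measurement stream, its state at
time `t` describes the physical situation at `t - latency`. Mode-B gating
therefore first propagates by `round(latency/dt)` steps (default 0.2 s =
20 steps at 100 Hz) to reach "now", then scans a further `horizon_steps`
= 14 steps (140 ms) for the upcoming end-inspiration. The compensated
display position is the latency-step prediction plus the baseline `C`.
With `latency_s = 0` the window starts at the current state.

## Gating

A prompt candidate at step `k` requires, on the latency-compensated
prediction series:

1. a + → − zero-crossing of predicted velocity within the 14-step
   look-ahead window, persisting for 3 consecutive samples (transient
   crossings during convergence do not persist);
2. displacement within 10% of the running cycle maximum and not falling
   over the last 10 samples (tolerance 5% of the cycle range);
3. at least `refractory_s` = 2 s (≈ the shortest plausible half-cycle at
   20 breaths/min) since the previous prompt, and at least `warmup_s` =
   1 s into the run.

Cycle boundaries for template learning are − → + velocity crossings of a
0.15 s-smoothed velocity, accepted only near the running cycle minimum
(30% band): raw zero-crossings of noisy velocity otherwise produce false
boundaries mid-descent. Each completed valley-to-valley cycle is resampled
to 100 points, amplitude-normalized to [0, 1] and averaged over the last 5
cycles into the template, which records mean amplitude, mean period and
the peak-position fraction.

**Dual validation**: a candidate is emitted only if the cycle-so-far
(i) correlates with the matching template prefix at ≥ 0.8 (normalized
cross-correlation of amplitude-normalized shapes), (ii) has peak-to-peak
amplitude within ±50% of the template mean (rejects 3× pulse artifacts),
and (iii) reaches the candidate at an elapsed time within ±30% of the
template's expected time-to-peak (rejects stretched cycles). Before two
cycles have completed the template is not ready and the primary rule alone
decides, flagged on the event. Failed validation suppresses the prompt
(and is logged on the engine) rather than merely flagging it; the
refractory clock is not advanced by suppressed candidates, so a later
valid candidate in the same cycle can still fire.

Mode A (baseline) detects instantaneously on the raw delayed measurement:
a 5-sample trailing mean, a 10-sample trailing finite-difference velocity,
and the same near-maximum gate, template validation and refractory. Its
prompts trail the true peak by the latency plus the causal smoothing lag.

## Synthetic respiration

The generator emulates a motion platform at the displacement-signal level:

* `sine`: `A sin(2*pi*t/T)`, defaults 10 mm / 5 s (adult resting
  breathing); the deterministic benchmark.
* `regular` / `shallow`: cycle-by-cycle raised-cosine breaths
  `a (1 - cos(2*pi*tau/T'))/2` — zero at end-expiration with a realistic
  end-inspiration plateau — with per-cycle `a, T'` drawn as
  `nominal * (1 + jitter * N(0,1))`, clipped positive. Shallow breathing
  uses a 3–5 mm nominal amplitude (4 mm in tests) versus 10 mm normal.
* `irregular`: additionally superimposes half-sine pulse artifacts
  (Poisson arrivals, default 4/min, 5 mm, 0.3 s — coughs/swallows; onset
  times recorded in `meta`) and a ±20% linear amplitude ramp across the
  run (non-stationarity).
* corruptions: i.i.d. Gaussian sensor noise (default 0.3 mm — the noise
  and drift scales of a physical chain are not prescribed anywhere, so
  these are realistic, configurable placeholders); a sample-shift latency
  with leading-edge hold (fractional latencies rounded to the grid and
  recorded in `meta`); and a slow sinusoidal baseline drift (default
  1 mm over 120 s) that warns when its period is within 5× the breathing
  period.

All randomness flows from one integer seed through named sub-streams
(`subseed(seed, stage)`), so runs are bit-reproducible and stages can be
re-run independently. What the generator does **not** model: airflow and
pneumatic physics, 3-D chest-surface motion (motion is the 1-D principal
axis, embedded along a configurable unit vector for 3-D error metrics),
occlusion/dropout of the tracker, and operator reaction time. Passing
tests therefore demonstrate algorithmic correctness under controlled
conditions, not clinical performance.

## Classification

`Ma` is computed literally as the mean absolute sample value (a DC offset
inflates it; an optional `detrend` flag subtracts the mean first).
`Ia`/`Ip` use population standard deviations (ddof = 0; switchable), and
quartiles use linear interpolation between order statistics. Extremum
detection shares the gating conventions (prominence ≥ 20% of global range,
≥ 1 s separation, alternation enforced by keeping the more extreme of
same-type neighbors). Boundary rules: *irregular* requires strictly
exceeding a median; *shallow* is `Ma ≤ q25`.

The median/quartile rule is relative to a signal collection, and a median
threshold can only sit above every regular signal's index when irregular
signals are well represented: with a single outlier among N, the largest
regular index necessarily exceeds the median of the rest. The archetype
suite in the tests therefore uses a balanced collection (4 regular/shallow
+ 4 irregular), which is the regime in which the rule is meaningful.

## Registration

The closed-form SVD solution for `min sum ||R p_i + t - q_i||^2`:
covariance of centered correspondences, SVD, reflection corrected by the
determinant sign, `t` from the centroids. Scale is fixed to 1 (both frames
are metric mm); the similarity variant is available behind `with_scale`.
Degenerate geometry is refused when the second singular value of the
centered source drops below 1e-6 of the largest. The rotation is
cross-checked in tests against an independent Wahba solver
(`scipy.spatial.transform.Rotation.align_vectors`) and recovers random
rigid transforms on the five-fiducial plate to ≤ 1e-9 mm RMSE.

## Evaluation protocol

Truth is corrupted once per seed (latency first — the display chain delays
physical motion — then sensor noise) and the identical stream feeds both
modes. Displayed position: Mode A = raw delayed measurement; Mode B =
latency-compensated prediction + baseline. `TPE(t)` is the Euclidean
distance between the 3-D embeddings of truth and display; summaries use
the population convention, so `RMSE^2 = mean^2 + sd^2` exactly. Gold
end-inspiration times come from prominence-filtered peaks of the clean
signal with 3-point parabolic sub-sample refinement. Prompt matching is
one-to-one nearest-neighbor with matches farther than half the median
cycle discarded; unprompted cycles count against accuracy but are excluded
from the `dT` statistics (both conventions are choices; the per-cycle
series is exposed for any alternative analysis). The ±300 ms accuracy
window is configurable; it comfortably contains both the uncompensated
~200 ms delay and the predictive ~110 ms lead, so accuracy differences
reflect missed or spurious prompts rather than the window edge.

Problem sizes used by the shipped benchmarks: the sine benchmark runs
~62 cycles (308 s at 100 Hz), the regular-breathing benchmark ~100 cycles
per seed across 5 seeds, and the mode-ordering comparison 10 seeds of
~30 cycles each — large enough for stable percentages while keeping any
single run in the seconds range.

## Known limitations

* Prediction quality degrades on strongly irregular breathing (pulse
  artifacts, non-stationary amplitude): the oscillator model is
  single-frequency, and the template bands are tuned to reject — not
  track — artifacts. This mirrors the intended clinical use (prompting
  during stable breathing).
* On non-respiratory input (e.g. a monotone ramp) the predictive detector
  can emit at most a transient candidate while the state estimates
  converge; the instantaneous detector emits none.
* The first prompt of a run cannot precede filter convergence; candidates
  are suppressed during the first second.
* `Ia` is offset-sensitive by construction (extremum *values*, not
  prominences); `Ip` is offset- and shift-invariant.
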