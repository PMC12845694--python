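"""End-inspiration gating: anticipatory prompts with template validation.

End-inspiration (the displacement maximum of each breath) is the preferred
puncture window.  Two detection modes mirror the evaluation protocol:

* **Mode A** (baseline, filter disabled): instantaneous detection on the raw
  delayed measurement — finite-difference velocity zero-crossing from + to -.
  Prompts necessarily trail the true peak by the measurement latency.
* **Mode B** (predictive): the adaptive Kalman filter's multi-step prediction
  is scanned for an upcoming velocity zero-crossing.  The known display
  latency is compensated first, then the gating horizon looks further ahead,
  so prompts lead the true peak by roughly ``horizon_steps * dt``.

Every primary detection is cross-checked against a personalized respiratory
template learned online from recent completed cycles (dual validation):
shape similarity by normalized cross-correlation plus amplitude and timing
bands.  Candidates failing validation are suppressed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .kalman import FilterConfig, FilterTrace, run_filter
from .signal import Signal

__all__ = [
    "GatingConfig",
    "RespiratoryTemplate",
    "GatingEvent",
    "Candidate",
    "learn_template",
    "validate_event",
    "detect_candidates",
    "run_gating",
]


@dataclass
class GatingConfig:
    """Gating parameters.

    ``latency_s`` is the known measurement/display latency the predictive
    mode compensates before applying its look-ahead window of
    ``horizon_steps`` samples; with ``latency_s = 0`` the prediction window
    starts at the current filter state.  ``refractory_s`` enforces a minimum
    spacing between prompts (about the shortest plausible half-cycle at 20
    breaths/min).  Template bands: a candidate cycle must stay within
    ``(1 +- amplitude_band_frac)`` of the learned mean amplitude and
    ``(1 +- period_band_frac)`` of the learned time-to-peak.
    """

    horizon_steps: int = 14
    latency_s: float = 0.2
    refractory_s: float = 2.0
    template_cycles: int = 5
    template_points: int = 100
    similarity_threshold: float = 0.8
    amplitude_band_frac: float = 0.5
    period_band_frac: float = 0.3
    trend_window_steps: int = 10
    peak_proximity_frac: float = 0.9
    trend_tolerance_frac: float = 0.05
    persistence_steps: int = 3
    warmup_s: float = 1.0
    valley_smooth_s: float = 0.15
    valley_proximity_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")


@dataclass
class RespiratoryTemplate:
    """Mean recent breathing cycle, amplitude-normalized to [0, 1]."""

    shape: np.ndarray
    mean_amplitude: float
    mean_period: float
    n_cycles: int

    @property
    def ready(self) -> bool:
        return self.n_cycles >= 2

    @property
    def peak_frac(self) -> float:
        """Fraction of the cycle at which the template peaks."""
        if self.shape.size == 0:
            return 0.5
        return float(np.argmax(self.shape)) / max(self.shape.size - 1, 1)


@dataclass
class GatingEvent:
    """An emitted end-inspiration prompt."""

    t_prompt: float
    t_predicted_peak: float
    validated: bool
    score: float
    mode: str
    template_ready: bool = True


@dataclass
class Candidate:
    """A primary detection awaiting template validation."""

    k: int
    t: float
    h_star: int              # look-ahead steps to the predicted peak (0 for mode A)
    t_predicted_peak: float


def _resample(values: np.ndarray, n_points: int) -> np.ndarray:
    if values.size == 1:
        return np.full(n_points, values[0])
    xp = np.linspace(0.0, 1.0, values.size)
    return np.interp(np.linspace(0.0, 1.0, n_points), xp, values)


def _normalize(shape: np.ndarray) -> np.ndarray:
    rng = np.ptp(shape)
    if rng < 1e-12:
        return np.zeros_like(shape)
    return (shape - shape.min()) / rng


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation (Pearson) of two equal-length vectors."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(a @ b / (na * nb))


def learn_template(recent_cycles: list[Signal],
                   config: GatingConfig | None = None) -> RespiratoryTemplate:
    """Average the recent valley-to-valley cycles into a reference template.

    Each cycle is resampled to a fixed number of points, amplitude-normalized
    to [0, 1] and averaged; mean amplitude (peak-to-peak) and mean period are
    recorded.  With fewer than 2 cycles the template is returned not-ready
    and validation falls back to the primary rule alone.
    """
    cfg = config if config is not None else GatingConfig()
    n_points = cfg.template_points
    if not recent_cycles:
        return RespiratoryTemplate(np.zeros(n_points), 0.0, 0.0, 0)
    shapes = []
    amps = []
    periods = []
    for cyc in recent_cycles:
        shapes.append(_normalize(_resample(cyc.values, n_points)))
        amps.append(float(np.ptp(cyc.values)))
        periods.append(cyc.n * cyc.dt)
    return RespiratoryTemplate(np.mean(shapes, axis=0), float(np.mean(amps)),
                               float(np.mean(periods)), len(recent_cycles))


def validate_event(candidate: Candidate, template: RespiratoryTemplate,
                   current_cycle: Signal,
                   config: GatingConfig | None = None) -> tuple[bool, float]:
    """Dual validation of a primary detection against the learned template.

    The cycle-so-far (from the last valley to the candidate) must
    simultaneously (i) correlate with the matching template prefix at or
    above ``similarity_threshold``, (ii) have a peak-to-peak amplitude within
    the amplitude band of the template mean, and (iii) reach the candidate at
    an elapsed time within the period band of the template's expected
    time-to-peak.  A not-ready template passes the candidate on the primary
    rule alone (flagged via the returned NaN score).
    """
    cfg = config if config is not None else GatingConfig()
    if template is None or not template.ready:
        return True, float("nan")

    elapsed = current_cycle.n * current_cycle.dt
    expected_t_peak = template.peak_frac * template.mean_period
    if expected_t_peak <= 0:
        expected_t_peak = 0.5 * template.mean_period
    period_ok = (1.0 - cfg.period_band_frac) <= elapsed / expected_t_peak \
        <= (1.0 + cfg.period_band_frac)

    amp = float(np.ptp(current_cycle.values))
    amp_ok = template.mean_amplitude > 0 and \
        (1.0 - cfg.amplitude_band_frac) <= amp / template.mean_amplitude \
        <= (1.0 + cfg.amplitude_band_frac)

    frac = np.clip(elapsed / max(template.mean_period, 1e-9), 0.05, 1.0)
    L = max(int(round(frac * cfg.template_points)), 3)
    cur = _normalize(_resample(current_cycle.values, L))
    score = _ncc(cur, template.shape[:L])

    return bool(score >= cfg.similarity_threshold and amp_ok and period_ok), score


class _GatingEngine:
    """Causal single-pass detector over displacement/velocity series.

    ``d``/``v`` are the mode's working displacement and velocity series
    (latency-compensated predictions for mode B, smoothed finite differences
    of the raw measurement for mode A).  ``h_star`` gives, per step, the
    look-ahead (in samples) to a predicted velocity zero-crossing, or -1.
    """

    def __init__(self, t0: float, dt: float, d: np.ndarray, v: np.ndarray,
                 h_star: np.ndarray, mode: str, config: GatingConfig,
                 validate: bool = True):
        self.t0, self.dt = t0, dt
        self.d, self.v = d, v
        self.h_star = h_star
        self.mode = mode
        self.cfg = config
        self.validate = validate
        self.events: list[GatingEvent] = []
        self.candidates: list[Candidate] = []
        self.rejected: list[GatingEvent] = []
        self.template: RespiratoryTemplate | None = None

    def run(self) -> list[GatingEvent]:
        cfg = self.cfg
        dt = self.dt
        n = self.d.size
        refr = cfg.refractory_s
        tw = cfg.trend_window_steps
        min_valley_gap = int(round(refr / dt))

        # heavier trailing smoothing of the working velocity, used only for
        # valley detection (cycle segmentation tolerates the small lag)
        w = max(1, int(round(cfg.valley_smooth_s / dt)))
        vs = np.convolve(self.v, np.ones(w) / w, mode="full")[:n]
        vs[:w - 1] = self.v[:w - 1]

        cycles: deque[Signal] = deque(maxlen=cfg.template_cycles)
        cycle_start = 0
        last_valley_k = -min_valley_gap
        cycle_max = -np.inf
        cycle_min = np.inf
        last_event_t = -np.inf
        last_candidate_t = -np.inf
        n_persist = 0

        for k in range(n):
            dk = self.d[k]
            cycle_max = max(cycle_max, dk)
            cycle_min = min(cycle_min, dk)
            rng = cycle_max - cycle_min

            # valley: smoothed working velocity crosses - -> + near the
            # running cycle minimum => a cycle completed
            if k > 0 and vs[k - 1] <= 0.0 < vs[k] \
                    and k - last_valley_k >= min_valley_gap \
                    and (rng <= 0 or dk <= cycle_min + cfg.valley_proximity_frac * rng):
                if k - cycle_start >= 3 and last_valley_k >= 0:
                    cycles.append(Signal(self.t0 + cycle_start * dt, dt,
                                         self.d[cycle_start:k].copy()))
                    self.template = learn_template(list(cycles), cfg)
                cycle_start = k
                last_valley_k = k
                cycle_max = dk
                cycle_min = dk

            hs = self.h_star[k]
            n_persist = n_persist + 1 if hs >= 0 else 0
            # persistence applies to the predictive window only; the
            # instantaneous mode-A crossing fires on a single sample
            need_persist = cfg.persistence_steps if self.mode == "B" else 1
            if hs < 0 or n_persist < need_persist:
                continue
            t_k = self.t0 + k * dt
            if t_k - self.t0 < cfg.warmup_s:
                continue
            if t_k - last_event_t < refr or t_k - last_candidate_t < refr:
                continue
            # upward-trend gate: near the running cycle maximum and not falling
            if rng > 0 and dk < cycle_max - (1.0 - cfg.peak_proximity_frac) * rng:
                continue
            if k >= tw and dk < self.d[k - tw] - cfg.trend_tolerance_frac * max(rng, 1e-9):
                continue

            cand = Candidate(k, t_k, int(hs), t_k + int(hs) * dt)
            self.candidates.append(cand)
            if not self.validate:
                last_candidate_t = t_k
            if self.validate:
                seg = Signal(self.t0 + cycle_start * dt, dt,
                             self.d[cycle_start:k + 1].copy())
                ok, score = validate_event(cand, self.template, seg, cfg)
                ready = self.template is not None and self.template.ready
                ev = GatingEvent(t_k, cand.t_predicted_peak, ok, score,
                                 self.mode, template_ready=ready)
                if ok:
                    self.events.append(ev)
                    last_event_t = t_k
                else:
                    self.rejected.append(ev)
            else:
                self.events.append(GatingEvent(t_k, cand.t_predicted_peak,
                                               True, float("nan"), self.mode))
                last_event_t = t_k
        return self.events


def _crossing_lookahead(v_now: np.ndarray, pred_v_window: np.ndarray) -> np.ndarray:
    """Per-step look-ahead (samples) to the first predicted + -> - velocity
    zero-crossing within the horizon window, or -1 when there is none."""
    W = np.column_stack([v_now, pred_v_window])
    cross = (W[:, :-1] > 0.0) & (W[:, 1:] <= 0.0)
    any_cross = cross.any(axis=1)
    first = cross.argmax(axis=1)  # first True column where any
    out = np.where(any_cross, first + 1, -1)
    return out.astype(int)


def _mode_b_engine(trace: FilterTrace, config: GatingConfig,
                   validate: bool = True) -> _GatingEngine:
    lat = int(round(config.latency_s / trace.dt))
    H = config.horizon_steps
    if trace.pred_x.shape[1] < lat + H:
        raise ValueError(
            f"trace horizon {trace.pred_x.shape[1]} < latency+horizon {lat + H}; "
            "re-run the filter with a larger horizon_steps")
    if lat >= 1:
        d = trace.pred_x[:, lat - 1]
        v = trace.pred_v[:, lat - 1]
    else:
        d = trace.xr
        v = trace.vr
    h_star = _crossing_lookahead(v, trace.pred_v[:, lat:lat + H])
    return _GatingEngine(trace.t0, trace.dt, d, v, h_star, "B", config, validate)


def _mode_a_engine(measured: Signal, config: GatingConfig,
                   validate: bool = True) -> _GatingEngine:
    # light trailing smoothing, then a trailing finite-difference velocity:
    # fully causal, so mode-A prompts trail the true peak by latency plus
    # the smoothing/differencing lag.
    v_raw = measured.values
    kernel = np.ones(5) / 5.0
    s = np.convolve(v_raw, kernel, mode="full")[:v_raw.size]
    s[:4] = v_raw[:4]  # warm-up: undefined trailing window
    lag = 10
    v = np.zeros_like(s)
    v[lag:] = (s[lag:] - s[:-lag]) / (lag * measured.dt)
    # instantaneous crossing: look-ahead 0
    h_star = np.full(s.size, -1, dtype=int)
    crossing = (v[:-1] > 0.0) & (v[1:] <= 0.0)
    h_star[1:][crossing] = 0
    return _GatingEngine(measured.t0, measured.dt, s, v, h_star, "A",
                         config, validate)


def detect_candidates(trace: FilterTrace,
                      config: GatingConfig | None = None) -> list[Candidate]:
    """Primary (unvalidated) end-inspiration candidates from a filter trace.

    A candidate fires at step k when the predicted velocity crosses zero from
    + to - within the look-ahead window, the working displacement is near the
    running cycle maximum and non-decreasing over the trend window, and the
    refractory period has elapsed.
    """
    cfg = config if config is not None else GatingConfig()
    engine = _mode_b_engine(trace, cfg, validate=False)
    engine.run()
    return engine.candidates


def run_gating(measured: Signal, mode: str,
               fconfig: FilterConfig | None = None,
               gconfig: GatingConfig | None = None,
               trace: FilterTrace | None = None) -> list[GatingEvent]:
    """Detect and validate end-inspiration prompts on a measured stream.

    Mode ``"A"`` detects instantaneously on the (delayed) measurement; mode
    ``"B"`` runs the adaptive filter (or reuses a supplied ``trace``) and
    prompts ahead using latency-compensated multi-step predictions.  Events
    are causal and separated by at least the refractory period; candidates
    failing template validation are suppressed.
    """
    if mode not in ("A", "B"):
        raise ValueError(f"mode must be 'A' or 'B', got {mode!r}")
    gcfg = gconfig if gconfig is not None else GatingConfig()
    if mode == "A":
        engine = _mode_a_engine(measured, gcfg)
        return engine.run()
    fcfg = fconfig if fconfig is not None else FilterConfig(dt=measured.dt)
    lat = int(round(gcfg.latency_s / measured.dt))
    need = lat + gcfg.horizon_steps
    if trace is None:
        if fcfg.horizon_steps < need:
            fcfg = replace(fcfg, horizon_steps=need)
        trace = run_filter(measured, fcfg)
    engine = _mode_b_engine(trace, gcfg)
    return engine.run()
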