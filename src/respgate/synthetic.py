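"""Synthetic respiratory waveform generation and measurement corruption.

Stands in, at the displacement-signal level, for a physical respiratory
motion platform: ground-truth waveforms (ideal sine, regular, shallow and
irregular breathing) plus the corruptions a real measurement chain adds —
Gaussian sensor noise, slow baseline drift and a display/measurement latency.

Amplitude and period conventions follow resting adult respiration: 10 mm
displacement with a 5 s period for normal breathing, 3-5 mm for shallow
breathing, periods in the 3-6 s range (10-20 breaths/min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import Signal, subseed

__all__ = [
    "SimulationSpec",
    "gen_sine",
    "gen_breathing",
    "add_noise",
    "apply_latency",
    "add_baseline_drift",
    "simulate",
]

PATTERNS = ("sine", "regular", "shallow", "irregular")


@dataclass
class SimulationSpec:
    """Parameters of a simulated breathing run.

    ``pattern`` selects the waveform family.  ``sine`` is the deterministic
    benchmark; ``regular``/``shallow``/``irregular`` are built cycle by cycle
    from raised-cosine breaths whose amplitude and period are jittered
    cycle-to-cycle.  ``irregular`` additionally superimposes random pulse
    artifacts (Poisson arrivals) and a slow linear amplitude trend
    (non-stationarity).
    """

    pattern: str = "sine"
    amplitude_mm: float = 10.0
    period_s: float = 5.0
    duration_s: float = 60.0
    dt_s: float = 0.01
    t0_s: float = 0.0
    amplitude_jitter_frac: float = 0.0
    period_jitter_frac: float = 0.0
    pulse_rate_per_min: float = 4.0      # irregular only
    pulse_amplitude_mm: float = 5.0      # irregular only
    pulse_width_s: float = 0.3           # irregular only
    trend_frac: float = 0.2              # irregular only: +-20% amplitude ramp
    drift_amplitude_mm: float = 0.0
    drift_period_s: float = 120.0
    noise_sd_mm: float = 0.0
    latency_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.amplitude_jitter_frac < 0 or self.period_jitter_frac < 0:
            raise ValueError("jitter fractions must be >= 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")


def gen_sine(spec: SimulationSpec) -> Signal:
    """Ideal sinusoidal breathing: ``A * sin(2*pi*t / T)``.

    No jitter, noise or drift is applied; corruption is composed explicitly
    via :func:`add_noise` / :func:`apply_latency` / :func:`add_baseline_drift`.
    """
    if spec.pattern != "sine":
        raise ValueError(f"gen_sine requires pattern='sine', got {spec.pattern!r}")
    n = int(round(spec.duration_s / spec.dt_s))
    if n < 1:
        raise ValueError("duration shorter than one sample")
    t = spec.t0_s + spec.dt_s * np.arange(n)
    values = spec.amplitude_mm * np.sin(2.0 * np.pi * t / spec.period_s)
    return Signal(spec.t0_s, spec.dt_s, values,
                  meta={"pattern": "sine", "amplitude_mm": spec.amplitude_mm,
                        "period_s": spec.period_s, "seed": spec.seed})


def gen_breathing(spec: SimulationSpec) -> Signal:
    """Cycle-by-cycle breathing waveform (regular / shallow / irregular).

    Each breath is a raised cosine ``a * (1 - cos(2*pi*tau/T)) / 2`` — zero at
    the cycle boundaries (end-expiration), peaking at ``a`` mid-cycle with a
    realistic end-inspiration plateau.  Per-cycle amplitude and period are
    drawn as ``nominal * (1 + jitter * N(0,1))``, clipped positive.

    ``irregular`` adds Poisson-arriving half-sine pulse artifacts (coughs,
    swallows) and a slow linear amplitude trend; pulse onset times are stored
    in ``meta['pulse_times']`` so injected artifacts can be audited.
    """
    if spec.pattern not in ("regular", "shallow", "irregular"):
        raise ValueError(f"gen_breathing requires a breathing pattern, got {spec.pattern!r}")
    if spec.duration_s < spec.period_s:
        raise ValueError("duration_s must cover at least one breathing cycle")

    rng = np.random.default_rng(subseed(spec.seed, "cycles"))
    n = int(round(spec.duration_s / spec.dt_s))
    values = np.zeros(n)
    t_rel = spec.dt_s * np.arange(n)  # time relative to t0

    t_cycle = 0.0
    while t_cycle < spec.duration_s:
        amp = spec.amplitude_mm * (1.0 + spec.amplitude_jitter_frac * rng.standard_normal())
        per = spec.period_s * (1.0 + spec.period_jitter_frac * rng.standard_normal())
        amp = max(amp, 0.05 * spec.amplitude_mm)
        per = max(per, 0.2 * spec.period_s)
        if spec.pattern == "irregular":
            # slow linear amplitude ramp across the run (non-stationarity)
            frac = t_cycle / spec.duration_s
            amp *= 1.0 + spec.trend_frac * (2.0 * frac - 1.0)
        i0 = int(np.ceil(t_cycle / spec.dt_s - 1e-9))
        i1 = min(int(np.ceil((t_cycle + per) / spec.dt_s - 1e-9)), n)
        tau = t_rel[i0:i1] - t_cycle
        values[i0:i1] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / per))
        t_cycle += per

    pulse_times: list[float] = []
    if spec.pattern == "irregular" and spec.pulse_rate_per_min > 0:
        prng = np.random.default_rng(subseed(spec.seed, "pulses"))
        n_pulses = prng.poisson(spec.pulse_rate_per_min * spec.duration_s / 60.0)
        starts = np.sort(prng.uniform(0.0, spec.duration_s - spec.pulse_width_s,
                                      size=n_pulses))
        for ts in starts:
            i0 = int(np.ceil(ts / spec.dt_s))
            i1 = min(int(np.floor((ts + spec.pulse_width_s) / spec.dt_s)) + 1, n)
            tau = t_rel[i0:i1] - ts
            values[i0:i1] += spec.pulse_amplitude_mm * np.sin(
                np.pi * tau / spec.pulse_width_s)
            pulse_times.append(float(ts))

    meta = {"pattern": spec.pattern, "amplitude_mm": spec.amplitude_mm,
            "period_s": spec.period_s, "seed": spec.seed}
    if spec.pattern == "irregular":
        meta["pulse_times"] = pulse_times
    return Signal(spec.t0_s, spec.dt_s, values, meta)


def add_noise(signal: Signal, noise_sd_mm: float, seed: int = 0) -> Signal:
    """Add i.i.d. zero-mean Gaussian measurement noise, seed-deterministic."""
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    if noise_sd_mm == 0:
        return signal.with_values(signal.values, noise_sd_mm=0.0)
    rng = np.random.default_rng(seed)
    out = signal.values + noise_sd_mm * rng.standard_normal(signal.n)
    return signal.with_values(out, noise_sd_mm=noise_sd_mm, noise_seed=int(seed))


def apply_latency(signal: Signal, latency_s: float) -> Signal:
    """Delay the stream by ``latency_s`` (rounded to whole samples).

    The leading ``k`` samples hold the first value; length is preserved, so
    the output models what a display with measurement latency would show at
    each true time.  A fractional latency is rounded to the nearest sample
    and the rounded value recorded in ``meta``.
    """
    if latency_s < 0:
        raise ValueError("latency_s must be >= 0")
    k = int(round(latency_s / signal.dt))
    if k >= signal.n:
        raise ValueError(f"latency {latency_s} s exceeds signal duration")
    meta_extra = {"latency_s": k * signal.dt}
    if abs(latency_s - k * signal.dt) > 1e-9:
        meta_extra["latency_requested_s"] = latency_s
    if k == 0:
        return signal.with_values(signal.values, **meta_extra)
    out = np.concatenate([np.full(k, signal.values[0]), signal.values[:-k]])
    return signal.with_values(out, **meta_extra)


def add_baseline_drift(signal: Signal, drift_amplitude_mm: float,
                       drift_period_s: float,
                       breathing_period_s: float | None = None) -> Signal:
    """Superimpose a slow sinusoidal baseline ``D * sin(2*pi*t/T_drift)``.

    Models the slowly varying non-respiratory offset (posture, platform
    drift) that the filter's baseline state absorbs.  Warns when the drift
    period is not well separated (< 5x) from the breathing period.
    """
    if drift_period_s <= 0:
        raise ValueError("drift_period_s must be positive")
    if breathing_period_s is not None and drift_period_s < 5.0 * breathing_period_s:
        warnings.warn("drift period is < 5x the breathing period; the baseline "
                      "state may alias respiratory motion", stacklevel=2)
    if drift_amplitude_mm == 0:
        return signal.with_values(signal.values)
    drift = drift_amplitude_mm * np.sin(2.0 * np.pi * signal.times / drift_period_s)
    return signal.with_values(signal.values + drift,
                              drift_amplitude_mm=drift_amplitude_mm,
                              drift_period_s=drift_period_s)


def simulate(spec: SimulationSpec) -> tuple[Signal, Signal]:
    """Generate ``(truth, measured)`` for a full simulation spec.

    ``truth`` is the clean waveform (plus baseline drift, which is real
    motion); ``measured`` is truth passed through the measurement chain:
    latency first (the tracking/display pipeline delays the physical
    motion), then additive sensor noise.
    """
    truth = gen_sine(spec) if spec.pattern == "sine" else gen_breathing(spec)
    if spec.drift_amplitude_mm:
        truth = add_baseline_drift(truth, spec.drift_amplitude_mm,
                                   spec.drift_period_s, spec.period_s)
    measured = apply_latency(truth, spec.latency_s)
    measured = add_noise(measured, spec.noise_sd_mm, subseed(spec.seed, "noise"))
    return truth, measured
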