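"""Adaptive Kalman filtering of respiratory displacement with multi-step prediction.

The respiratory stream is modeled by a three-state linear system

    x = (Xr, Vr, C)

where ``Xr`` is respiratory displacement [mm], ``Vr`` its velocity [mm/s] and
``C`` a slowly varying baseline offset [mm].  The transition matrix embeds a
harmonic oscillator at the instantaneous angular breathing frequency
``omega_r = 2*pi*f_r``:

    A = [[1,            dt, 0],
         [-omega^2*dt,  1,  0],
         [0,            0,  1]]

and the scalar observation is ``z = Xr + C + v``, ``v ~ N(0, R)``.

Adaptation closes three loops while filtering:

* ``f_r`` is re-estimated from peak-to-peak intervals of the filtered ``Xr``
  over a rolling 20 s buffer and smoothed by a 0.05 Hz one-pole IIR low-pass;
* ``R = sigma_noise^2`` tracks the high-frequency content of the raw stream
  (first differences over a short window);
* ``Q = diag(q0, omega_r^2, alpha * sigma_resp^2)`` couples process noise to
  the current frequency and to the long-term variance of ``Xr``.  Q is a
  continuous-time noise intensity; the per-step covariance used in the
  filter recursion is ``Q * dt``.

Multi-step prediction propagates the posterior state through ``A`` for
``h = 1..H_max`` steps, anticipating both respiratory phase and the display
latency of the navigation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .signal import Signal

__all__ = [
    "FilterConfig",
    "FilterState",
    "ModelMatrices",
    "FilterTrace",
    "build_transition",
    "build_process_noise",
    "predict_step",
    "update_step",
    "estimate_frequency",
    "estimate_measurement_noise",
    "multi_step_predict",
    "run_filter",
]

_H_OBS = np.array([1.0, 0.0, 1.0])
_NOISE_FLOOR_MM = 1e-6


@dataclass
class FilterConfig:
    """Tunable parameters of the adaptive filter.

    Defaults correspond to a 100 Hz tracking stream and resting adult
    breathing.  ``horizon_steps`` is the maximum prediction horizon ``H_max``
    (140 ms at 100 Hz); ``adapt_stride`` is the number of samples between
    refreshes of the frequency / noise / respiratory-variance estimates (the
    IIR frequency smoother still updates every sample).
    """

    dt: float = 0.01
    f0: float = 0.2
    f_min: float = 0.05
    f_max: float = 1.0
    freq_buffer_s: float = 20.0
    iir_cutoff_hz: float = 0.05
    alpha: float = 0.01
    q0: float = 1.0
    resp_buffer_s: float = 60.0
    noise_window_s: float = 5.0
    horizon_steps: int = 14
    adapt_stride: int = 10
    p0: float = 25.0
    init_window_s: float = 0.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.f_min <= self.f0 <= self.f_max):
            raise ValueError("require 0 < f_min <= f0 <= f_max")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        if self.adapt_stride < 1:
            raise ValueError("adapt_stride must be >= 1")

    @property
    def iir_coeff(self) -> float:
        """Per-sample one-pole coefficient ``a = 1 - exp(-2*pi*fc*dt)``."""
        return 1.0 - np.exp(-2.0 * np.pi * self.iir_cutoff_hz * self.dt)


@dataclass
class FilterState:
    """Posterior state: x = (Xr, Vr, C), covariance P, smoothed frequency."""

    x: np.ndarray
    P: np.ndarray
    f_r: float
    k: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.P = np.asarray(self.P, dtype=float).reshape(3, 3)

    @property
    def omega_r(self) -> float:
        return 2.0 * np.pi * self.f_r

    def check_health(self, tol: float = 1e-9) -> None:
        """Raise if P is asymmetric or indefinite beyond ``tol``."""
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.P)):
            raise FloatingPointError(f"non-finite filter state at step {self.k}")
        if np.max(np.abs(self.P - self.P.T)) > tol:
            raise FloatingPointError(f"covariance asymmetric at step {self.k}")
        if np.linalg.eigvalsh(self.P).min() < -tol:
            raise FloatingPointError(f"covariance indefinite at step {self.k}")


@dataclass
class ModelMatrices:
    """System matrices for one filter step: A, H_obs = [1,0,1], Q, R."""

    A: np.ndarray
    Q: np.ndarray
    R: float
    H_obs: np.ndarray = field(default_factory=lambda: _H_OBS.copy())

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        self.Q = np.asarray(self.Q, dtype=float).reshape(3, 3)
        if self.R <= 0:
            raise ValueError("R must be positive")


def build_transition(f_r: float, dt: float) -> np.ndarray:
    """Transition matrix of the harmonic-oscillator-plus-baseline model."""
    if f_r <= 0 or dt < 0:
        raise ValueError("require f_r > 0 and dt >= 0")
    omega = 2.0 * np.pi * f_r
    return np.array([[1.0, dt, 0.0],
                     [-omega * omega * dt, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])


def build_process_noise(omega_r: float, sigma2_resp: float,
                        config: FilterConfig | None = None) -> np.ndarray:
    """Q = diag(q0, omega_r^2, alpha * sigma2_resp).

    This is the process-noise *intensity* (continuous-time units);
    :func:`run_filter` discretizes it as ``Q * dt`` per step.
    """
    if sigma2_resp < 0:
        raise ValueError("sigma2_resp must be >= 0")
    cfg = config if config is not None else FilterConfig()
    return np.diag([cfg.q0, omega_r * omega_r, cfg.alpha * sigma2_resp])


def predict_step(state: FilterState, M: ModelMatrices) -> FilterState:
    """Time update: x- = A x, P- = A P A' + Q."""
    if not np.all(np.isfinite(state.x)):
        raise FloatingPointError("non-finite state entering predict_step")
    x = M.A @ state.x
    P = M.A @ state.P @ M.A.T + M.Q
    return replace(state, x=x, P=P)


def update_step(state: FilterState, z: float, M: ModelMatrices) -> FilterState:
    """Measurement update with scalar observation, Joseph-stabilized.

    The Joseph form ``P = (I-KH) P (I-KH)' + K R K'`` keeps P symmetric
    positive semidefinite over arbitrarily long runs.
    """
    if M.R <= 0:
        raise ValueError("R must be positive")
    h = M.H_obs
    nu = float(z) - h @ state.x
    Ph = state.P @ h
    S = h @ Ph + M.R
    K = Ph / S
    x = state.x + K * nu
    IKH = np.eye(3) - np.outer(K, h)
    P = IKH @ state.P @ IKH.T + M.R * np.outer(K, K)
    P = 0.5 * (P + P.T)
    return replace(state, x=x, P=P, k=state.k + 1)


def _raw_frequency(values: np.ndarray, dt: float, config: FilterConfig) -> float | None:
    """Peak-interval frequency of a buffer, or None if < 2 peaks found."""
    if values.size < 3:
        return None
    ptp = float(np.ptp(values))
    if ptp <= 1e-9:
        return None
    min_dist = max(1, int(round(1.0 / (config.f_max * dt))))
    peaks, _ = find_peaks(values, prominence=0.2 * ptp, distance=min_dist)
    if peaks.size < 2:
        return None
    f = 1.0 / (np.mean(np.diff(peaks)) * dt)
    return float(np.clip(f, config.f_min, config.f_max))


def estimate_frequency(filtered_buffer: Signal, config: FilterConfig,
                       prev_f: float, n_steps: int = 1) -> float:
    """Breathing frequency from a rolling buffer of the filtered signal.

    The raw estimate is the reciprocal of the mean peak-to-peak interval
    (prominence-filtered local maxima).  It is blended toward ``prev_f``
    through the 0.05 Hz one-pole IIR low-pass applied ``n_steps`` times (the
    number of samples elapsed since the previous call), then clamped to
    ``[f_min, f_max]``.  With fewer than two detectable peaks the previous
    value is returned unchanged.
    """
    if filtered_buffer is None or filtered_buffer.n == 0:
        return prev_f
    f_raw = _raw_frequency(filtered_buffer.values, filtered_buffer.dt, config)
    if f_raw is None:
        return prev_f
    decay = (1.0 - config.iir_coeff) ** max(int(n_steps), 0)
    f = f_raw + (prev_f - f_raw) * decay
    return float(np.clip(f, config.f_min, config.f_max))


def estimate_measurement_noise(raw_buffer: Signal | np.ndarray,
                               config: FilterConfig | None = None,
                               prev: float | None = None) -> float:
    """Measurement noise sd from first differences of the raw stream.

    For i.i.d. noise ``var(diff) = 2 sigma^2``, while the first difference of
    the smooth respiratory component is negligible at 100 Hz; hence
    ``sigma_noise = sd(diff(raw)) / sqrt(2)`` over the last ``noise_window_s``.
    Floored at 1e-6 mm; with fewer than 10 samples the previous estimate (or
    the floor at cold start) is returned.
    """
    cfg = config if config is not None else FilterConfig()
    values = raw_buffer.values if isinstance(raw_buffer, Signal) else np.asarray(raw_buffer)
    win = int(round(cfg.noise_window_s / cfg.dt))
    values = values[-win:]
    if values.size < 10:
        return prev if prev is not None else _NOISE_FLOOR_MM
    sigma = float(np.std(np.diff(values), ddof=0) / np.sqrt(2.0))
    return max(sigma, _NOISE_FLOOR_MM)


def multi_step_predict(state: FilterState, M: ModelMatrices, H_max: int) -> np.ndarray:
    """Predicted displacement X^r for horizons h = 1..H_max.

    Deterministic point prediction by iterated application of the transition
    matrix: ``x_{k+h|k} = A^h x_k``; returns the first state component per h.
    """
    if H_max < 1:
        raise ValueError("H_max must be >= 1")
    out = np.empty(H_max)
    x = state.x.copy()
    for h in range(H_max):
        x = M.A @ x
        out[h] = x[0]
    return out


@dataclass
class FilterTrace:
    """Per-step outputs of :func:`run_filter` (all arrays have input length).

    ``pred_x[k, j]`` / ``pred_v[k, j]`` hold the displacement / velocity
    predicted at step k for horizon ``h = j + 1`` (i.e. time ``t_k + (j+1)*dt``
    of the *measured* stream).
    """

    t0: float
    dt: float
    z: np.ndarray
    xr: np.ndarray
    vr: np.ndarray
    c: np.ndarray
    fr: np.ndarray
    innovation: np.ndarray
    P_diag: np.ndarray
    pred_x: np.ndarray
    pred_v: np.ndarray
    config: FilterConfig
    P_full: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def filtered(self) -> np.ndarray:
        """Filtered estimate of the observed quantity, Xr + C."""
        return self.xr + self.c

    def to_frame(self):
        """Trace as a DataFrame (column names match the trace CSV layout)."""
        import pandas as pd
        H = self.pred_x.shape[1]
        return pd.DataFrame({
            "time_s": self.times,
            "xr_mm": self.xr,
            "vr_mms": self.vr,
            "c_mm": self.c,
            "fr_hz": self.fr,
            "innovation_mm": self.innovation,
            f"pred_h{H}_mm": self.pred_x[:, -1],
        })


def run_filter(measured: Signal, config: FilterConfig | None = None,
               collect_P: bool = False) -> FilterTrace:
    """Run the adaptive filter causally over a measured displacement stream.

    Each step re-evaluates (every ``adapt_stride`` samples) the breathing
    frequency, the measurement-noise level and the long-term respiratory
    variance from past samples only, rebuilds A / Q / R, performs a
    predict-update cycle and propagates the multi-step prediction.  The
    initial state assigns the first sample entirely to the baseline,
    ``x0 = (0, 0, z0)``, so that truncating the input and re-running
    reproduces the trace prefix exactly (strict causality).
    """
    cfg = config if config is not None else FilterConfig()
    if abs(measured.dt - cfg.dt) > 1e-9:
        cfg = replace(cfg, dt=measured.dt)
    z = measured.values
    if np.any(np.isnan(z)):
        raise ValueError(f"NaN in input at sample {int(np.flatnonzero(np.isnan(z))[0])}")
    n = z.size
    dt = cfg.dt
    H = cfg.horizon_steps

    xr = np.empty(n); vr = np.empty(n); c = np.empty(n)
    fr = np.empty(n); innov = np.empty(n)
    P_diag = np.empty((n, 3))
    pred_x = np.empty((n, H)); pred_v = np.empty((n, H))
    P_full = np.empty((n, 3, 3)) if collect_P else None

    nbuf_freq = int(round(cfg.freq_buffer_s / dt))
    nbuf_noise = int(round(cfg.noise_window_s / dt))
    nbuf_resp = int(round(cfg.resp_buffer_s / dt))
    a_iir = cfg.iir_coeff

    f_r = float(np.clip(cfg.f0, cfg.f_min, cfg.f_max))
    f_raw = f_r
    sigma_noise = _NOISE_FLOOR_MM
    sigma2_resp = 0.0

    x = np.array([0.0, 0.0, z[0]])
    P = np.diag([cfg.p0, cfg.p0, cfg.p0])
    h_obs = _H_OBS
    I3 = np.eye(3)
    A = np.array([[1.0, dt, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    Q = np.diag([cfg.q0 * dt, 0.0, 0.0])  # per-step covariance = intensity * dt

    # two-point-differencing warm start for the unobserved velocity state:
    # once init_window_s of data has arrived, replace the (arbitrary) zero
    # initial velocity with a finite-difference slope of the measurements.
    # Strictly causal; greatly shortens first-cycle convergence.
    k_init = int(round(cfg.init_window_s / dt))

    for k in range(n):
        if k == k_init and 10 <= k_init < n:
            m = max(3, k_init // 10)
            x[1] = (z[k - m:k].mean() - z[:m].mean()) / ((k - m) * dt)
        if k > 0 and k % cfg.adapt_stride == 0:
            raw = _raw_frequency(xr[max(0, k - nbuf_freq):k], dt, cfg)
            if raw is not None:
                f_raw = raw
            j0 = max(0, k - nbuf_noise)
            if k - j0 >= 10:
                sigma_noise = max(float(np.std(np.diff(z[j0:k])) / np.sqrt(2.0)),
                                  _NOISE_FLOOR_MM)
            r0 = max(0, k - nbuf_resp)
            if k - r0 >= 2:
                sigma2_resp = float(np.var(xr[r0:k]))

        f_r += a_iir * (f_raw - f_r)
        f_r = min(max(f_r, cfg.f_min), cfg.f_max)
        omega = 2.0 * np.pi * f_r
        w2dt = omega * omega * dt
        A[1, 0] = -w2dt
        Q[1, 1] = omega * omega * dt
        Q[2, 2] = cfg.alpha * sigma2_resp * dt
        R = max(sigma_noise * sigma_noise, _NOISE_FLOOR_MM**2)

        # predict
        x = A @ x
        P = A @ P @ A.T + Q
        # update (Joseph form)
        nu = z[k] - x[0] - x[2]
        Ph = P @ h_obs
        S = Ph[0] + Ph[2] + R
        K = Ph / S
        x = x + K * nu
        IKH = I3 - np.outer(K, h_obs)
        P = IKH @ P @ IKH.T + R * np.outer(K, K)
        P = 0.5 * (P + P.T)

        xr[k] = x[0]; vr[k] = x[1]; c[k] = x[2]
        fr[k] = f_r; innov[k] = nu
        P_diag[k] = P[0, 0], P[1, 1], P[2, 2]
        if collect_P:
            P_full[k] = P

        xh = x[0]; vh = x[1]
        for j in range(H):
            xh, vh = xh + dt * vh, vh - w2dt * xh
            pred_x[k, j] = xh
            pred_v[k, j] = vh

    return FilterTrace(measured.t0, dt, z.copy(), xr, vr, c, fr, innov,
                       P_diag, pred_x, pred_v, cfg, P_full)
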