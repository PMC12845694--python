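"""Breathing-pattern indices and regular / shallow / irregular classification.

Three indices summarize a respiratory displacement signal S(t):

* mean amplitude  ``Ma = (1/N) * sum |S(t_i)|``  (overall breathing depth);
* amplitude irregularity  ``Ia = (sd({P_k}) + sd({V_l})) / 2``  — the average
  of the standard deviations of detected peak values and valley values;
* phase irregularity  ``Ip = (sd({Tp_k}) + sd({Tv_l})) / 2``  — the same for
  peak-to-peak and valley-to-valley interval durations.

Classification is threshold-based relative to a sample collection: a signal
is *irregular* when either irregularity index exceeds the collection median;
otherwise *shallow* when its Ma falls within the lowest quartile of the
collection, else *regular*.

Standard deviations are population (ddof=0) by default; Ma is computed on
the raw signal (a DC offset inflates it) unless ``detrend=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .signal import Signal

__all__ = [
    "BreathFeatures",
    "ClassThresholds",
    "detect_extrema",
    "mean_amplitude",
    "amplitude_irregularity",
    "phase_irregularity",
    "compute_features",
    "derive_thresholds",
    "classify",
]

LABELS = ("regular", "shallow", "irregular")


@dataclass
class BreathFeatures:
    """Per-signal indices plus the extrema they were computed from."""

    ma: float
    ia: float
    ip: float
    peaks: list = field(default_factory=list)      # (time_s, value_mm)
    valleys: list = field(default_factory=list)
    peak_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))
    valley_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))
    signal_id: str = ""


@dataclass
class ClassThresholds:
    """Collection-derived decision thresholds."""

    ia_median: float
    ip_median: float
    ma_q25: float


def detect_extrema(signal: Signal, min_prominence_frac: float = 0.2,
                   min_separation_s: float = 1.0) -> tuple[list, list]:
    """Prominence-filtered alternating peaks and valleys of a signal.

    Extrema must have prominence of at least ``min_prominence_frac`` of the
    global peak-to-peak range and be separated by ``min_separation_s``.
    Where two same-type extrema are adjacent after merging, the more extreme
    one is kept so the sequence strictly alternates.  A flat signal yields
    empty lists.
    """
    v = signal.values
    ptp = float(np.ptp(v))
    if ptp < 1e-12:
        return [], []
    dist = max(1, int(round(min_separation_s / signal.dt)))
    prom = min_prominence_frac * ptp
    ipk, _ = find_peaks(v, prominence=prom, distance=dist)
    ivl, _ = find_peaks(-v, prominence=prom, distance=dist)

    merged = sorted([(i, +1) for i in ipk] + [(i, -1) for i in ivl])
    kept: list[tuple[int, int]] = []
    for i, kind in merged:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = v[i] > v[j] if kind > 0 else v[i] < v[j]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))

    t = signal.times
    peaks = [(float(t[i]), float(v[i])) for i, kind in kept if kind > 0]
    valleys = [(float(t[i]), float(v[i])) for i, kind in kept if kind < 0]
    return peaks, valleys


def mean_amplitude(signal: Signal, detrend: bool = False) -> float:
    """Ma: mean absolute displacement, optionally after mean removal."""
    v = signal.values
    if detrend:
        v = v - v.mean()
    return float(np.mean(np.abs(v)))


def _sd(values: np.ndarray, ddof: int) -> float:
    return float(np.std(np.asarray(values, dtype=float), ddof=ddof))


def amplitude_irregularity(peaks: list, valleys: list, ddof: int = 0) -> float:
    """Ia: average of the sd of peak values and the sd of valley values.

    Requires at least two peaks and two valleys; otherwise 0 with a warning.
    """
    if len(peaks) < 2 or len(valleys) < 2:
        warnings.warn("fewer than 2 peaks/valleys; Ia set to 0", stacklevel=2)
        return 0.0
    pv = np.array([p[1] for p in peaks])
    vv = np.array([q[1] for q in valleys])
    return 0.5 * (_sd(pv, ddof) + _sd(vv, ddof))


def phase_irregularity(peaks: list, valleys: list, ddof: int = 0) -> float:
    """Ip: average of the sd of peak-to-peak and valley-to-valley intervals.

    Requires at least two intervals of each kind (3 peaks and 3 valleys);
    otherwise 0 with a warning.
    """
    if len(peaks) < 3 or len(valleys) < 3:
        warnings.warn("fewer than 2 cycle intervals; Ip set to 0", stacklevel=2)
        return 0.0
    tp = np.diff([p[0] for p in peaks])
    tv = np.diff([q[0] for q in valleys])
    return 0.5 * (_sd(tp, ddof) + _sd(tv, ddof))


def compute_features(signal: Signal, signal_id: str = "",
                     ddof: int = 0, detrend: bool = False) -> BreathFeatures:
    """All three indices plus supporting extrema for one signal."""
    peaks, valleys = detect_extrema(signal)
    return BreathFeatures(
        ma=mean_amplitude(signal, detrend=detrend),
        ia=amplitude_irregularity(peaks, valleys, ddof=ddof),
        ip=phase_irregularity(peaks, valleys, ddof=ddof),
        peaks=peaks,
        valleys=valleys,
        peak_intervals=np.diff([p[0] for p in peaks]) if len(peaks) > 1 else np.empty(0),
        valley_intervals=np.diff([q[0] for q in valleys]) if len(valleys) > 1 else np.empty(0),
        signal_id=signal_id,
    )


def derive_thresholds(features: list[BreathFeatures]) -> ClassThresholds:
    """Medians of Ia and Ip plus the 25th percentile of Ma over a collection.

    Percentiles use the linear-interpolation convention between order
    statistics.  At least 4 samples are required for the quartile to be
    meaningful.
    """
    if len(features) < 4:
        raise ValueError(f"need >= 4 feature samples, got {len(features)}")
    ia = [f.ia for f in features]
    ip = [f.ip for f in features]
    ma = [f.ma for f in features]
    return ClassThresholds(
        ia_median=float(np.median(ia)),
        ip_median=float(np.median(ip)),
        ma_q25=float(np.percentile(ma, 25.0)),
    )


def classify(f: BreathFeatures, th: ClassThresholds) -> str:
    """Label a signal as ``irregular``, ``shallow`` or ``regular``.

    Irregularity is checked first (strictly above either median); among the
    remaining signals those with Ma at or below the lowest quartile are
    shallow, the rest regular.
    """
    if f.ia > th.ia_median or f.ip > th.ip_median:
        return "irregular"
    if f.ma <= th.ma_q25:
        return "shallow"
    return "regular"
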