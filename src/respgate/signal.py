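"""Uniformly sampled 1-D respiratory displacement signals.

The whole toolkit operates on a single container: a uniformly sampled
displacement time series in millimetres.  A :class:`Signal` carries its start
time, sample interval and a free-form ``meta`` mapping used to record
provenance (waveform pattern, seed, injected latency, ...).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Signal", "subseed"]


@dataclass
class Signal:
    """A uniformly sampled displacement time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample [s].
    dt : float
        Sample interval [s]; must be positive.  The optical tracking chain
        this models runs at 100 Hz, so the conventional value is 0.01 s.
    values : ndarray
        Displacement samples [mm]; finite, length >= 1.
    meta : dict
        Free-form labels (pattern name, seed, latency rounding, ...).
    """

    t0: float
    dt: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + i*dt [s]."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample [s]."""
        return self.dt * (self.values.size - 1)

    def slice(self, i0: int, i1: int) -> "Signal":
        """Sub-signal covering sample indices ``[i0, i1)``."""
        if not (0 <= i0 < i1 <= self.n):
            raise IndexError(f"invalid slice [{i0}, {i1}) for length {self.n}")
        return Signal(self.t0 + i0 * self.dt, self.dt,
                      self.values[i0:i1].copy(), dict(self.meta))

    def with_values(self, values: np.ndarray, **meta) -> "Signal":
        """Copy with new samples and extra meta entries."""
        out = replace(self, values=np.asarray(values, dtype=float),
                      meta=dict(self.meta))
        out.meta.update(meta)
        return out


def subseed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage sub-seed from a single global seed.

    Stages of a pipeline (noise injection, breathing jitter, pulse arrivals)
    draw from independent streams so one stage can be re-run without
    disturbing the others.  The result is always below 2**31.
    """
    return (int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)
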