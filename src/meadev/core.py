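"""Core containers shared across the pipeline.

Conventions: times are seconds from recording start (0-based), voltages are
microvolts, burst intervals are half-open ``[t_start, t_end)`` with the
boundary values equal to the first/last spike time of the burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RecordingMeta",
    "VoltageRecording",
    "SpikeTrain",
    "Burst",
    "NetworkBurst",
]


@dataclass(frozen=True)
class RecordingMeta:
    """Identifies one electrode in one well on one recording day."""

    well: int = 0
    electrode: int = 1
    div: int = 0
    genotype: str = ""
    batch: str = ""

    def well_key(self) -> tuple:
        return (self.batch, self.well, self.div, self.genotype)


@dataclass
class VoltageRecording:
    """A single-electrode extracellular voltage trace (µV)."""

    samples: np.ndarray
    sampling_rate: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class SpikeTrain:
    """Sorted spike times (s) with per-spike peak amplitudes (µV)."""

    times: np.ndarray
    duration: float
    amplitudes: np.ndarray | None = None
    threshold: float | None = None
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
            if self.amplitudes.shape != self.times.shape:
                raise ValueError("amplitudes must match times")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate (Hz) over the whole recording."""
        return self.n_spikes / self.duration

    def subset(self, t0: float, t1: float) -> "SpikeTrain":
        keep = (self.times >= t0) & (self.times < t1)
        amps = self.amplitudes[keep] if self.amplitudes is not None else None
        return replace(self, times=self.times[keep], amplitudes=amps)


@dataclass(frozen=True)
class Burst:
    """A single-electrode burst; boundaries are first/last spike times."""

    t_start: float
    t_end: float
    n_spikes: int
    electrode: int = 1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class NetworkBurst:
    """Interval during which >= min_electrodes electrodes burst simultaneously."""

    t_start: float
    t_end: float
    electrodes: frozenset[int]
    n_spikes: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)


def as_train(times: Sequence[float], duration: float, **kw) -> SpikeTrain:
    """Convenience constructor used heavily in tests."""
    return SpikeTrain(times=np.asarray(list(times), dtype=float), duration=duration, **kw)
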