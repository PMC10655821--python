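"""Adaptive-threshold spike detection and electrode/well activity rules.

Each electrode gets its own threshold: ``noise_multiplier`` (default 5) times
the sample standard deviation of the baseline noise in the first
``baseline_window`` seconds (default 1 s) of its trace.  A spike is
registered at each negative-going crossing of ``-threshold``; the spike time
is placed at the extremum within ``dead_time`` after the crossing, the
amplitude is the absolute extremum, and further crossings within
``dead_time`` are absorbed into the same spike.

Activity rules: an electrode is *active* when it fires >= 10 spikes/min and
at least one spike reaches 20 µV; a well is active when at least one of its
electrodes is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import RecordingMeta, SpikeTrain, VoltageRecording

__all__ = [
    "DetectionParams",
    "estimate_noise_sd",
    "detect_spikes",
    "electrode_is_active",
    "well_is_active",
]

#: activity criterion: minimum firing rate (spikes per minute)
MIN_SPIKES_PER_MIN = 10.0
#: activity criterion: minimum spike amplitude (µV)
MIN_AMPLITUDE_UV = 20.0


@dataclass(frozen=True)
class DetectionParams:
    noise_multiplier: float = 5.0
    baseline_window: float = 1.0
    dead_time: float = 0.002
    polarity: str = "negative"  # or "both"
    rate_bin: float = 1.0       # bin width for rate features (s)
    robust_baseline: bool = False  # MAD-based SD for contaminated baselines

    def __post_init__(self) -> None:
        if self.noise_multiplier <= 0:
            raise ValueError("noise_multiplier must be positive")
        if self.dead_time <= 0:
            raise ValueError("dead_time must be positive")
        if self.polarity not in ("negative", "both"):
            raise ValueError("polarity must be 'negative' or 'both'")


def estimate_noise_sd(rec: VoltageRecording,
                      params: DetectionParams | None = None) -> float:
    """Sample SD of the first ``baseline_window`` seconds of the trace (µV)."""
    params = params or DetectionParams()
    n = int(round(params.baseline_window * rec.sampling_rate))
    if rec.samples.size < n:
        raise ValueError(
            f"trace ({rec.samples.size} samples) shorter than the "
            f"{params.baseline_window} s baseline window")
    base = rec.samples[:n]
    if params.robust_baseline:
        return float(np.median(np.abs(base - np.median(base))) / 0.6745)
    return float(np.std(base, ddof=1))


def detect_spikes(rec: VoltageRecording,
                  params: DetectionParams | None = None) -> SpikeTrain:
    """Threshold-crossing spike detection on one voltage trace."""
    params = params or DetectionParams()
    x = rec.samples
    if x.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    sd = estimate_noise_sd(rec, params)
    thr = params.noise_multiplier * sd
    fs = rec.sampling_rate
    dead = max(1, int(round(params.dead_time * fs)))

    below = x < -thr
    if params.polarity == "both":
        below = below | (x > thr)
    # crossing: sample i beyond threshold while sample i-1 was not
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.r_[0, crossings]

    times, amps = [], []
    last = -dead - 1
    for c in crossings:
        if c - last < dead:
            continue  # absorbed into the previous spike's dead time
        seg = x[c:c + dead]
        if params.polarity == "both" and x[c] > thr:
            k = int(np.argmax(seg))
        else:
            k = int(np.argmin(seg))
        times.append((c + k) / fs)
        amps.append(abs(float(seg[k])))
        last = c
    return SpikeTrain(times=np.asarray(times), duration=rec.duration,
                      amplitudes=np.asarray(amps), threshold=thr,
                      meta=rec.meta)


def electrode_is_active(train: SpikeTrain) -> bool:
    """True iff rate >= 10 spikes/min and some spike amplitude >= 20 µV.

    The amplitude criterion gates the electrode (any spike reaching 20 µV),
    not individual spikes.  Trains without amplitude information (e.g. raw
    generator output fed in at the spike-train level) fail the amplitude
    criterion only if amplitudes are present and all below 20 µV.
    """
    if train.duration <= 0:
        raise ValueError("train duration must be positive")
    if train.n_spikes * 60.0 / train.duration < MIN_SPIKES_PER_MIN:
        return False
    if train.amplitudes is not None and train.amplitudes.size:
        return bool(np.max(train.amplitudes) >= MIN_AMPLITUDE_UV)
    return train.n_spikes > 0


def well_is_active(trains: Iterable[SpikeTrain]) -> bool:
    """A well is active when at least one electrode is active."""
    return any(electrode_is_active(t) for t in trains)
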