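"""Single-electrode burst detection (max-interval method) and network bursts.

The max-interval convention runs in three phases:

1. *detect* -- open a candidate burst at spike ``i`` when the inter-spike
   interval to the next spike is <= ``max_isi_start``; keep extending while
   the running ISI is <= ``max_isi_end``.
2. *merge*  -- fuse consecutive candidates whose gap (start of the next minus
   end of the previous) is smaller than ``min_ibi``; spikes lying between the
   fused candidates are absorbed into the merged burst.
3. *filter* -- drop candidates shorter than ``min_duration`` or containing
   fewer than ``min_spikes`` spikes.

The default parameters are the standard multi-well MEA settings: 50 ms
start/end ISI, 100 ms minimum inter-burst interval, 50 ms minimum duration
and 4 spikes minimum.

A network burst is any maximal interval during which at least
``min_electrodes`` (default 3 of 12) electrodes are simultaneously inside a
single-electrode burst; the electrode set is the union of electrodes bursting
during the interval, and network bursts separated by less than ``min_ibi``
are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Burst, NetworkBurst, SpikeTrain

__all__ = ["BurstParams", "detect_bursts", "detect_network_bursts"]


@dataclass(frozen=True)
class BurstParams:
    max_isi_start: float = 0.050
    max_isi_end: float = 0.050
    min_ibi: float = 0.100
    min_duration: float = 0.050
    min_spikes: int = 4

    def __post_init__(self) -> None:
        if min(self.max_isi_start, self.max_isi_end, self.min_ibi,
               self.min_duration) <= 0 or self.min_spikes < 1:
            raise ValueError("all burst parameters must be positive")
        if self.min_ibi < self.max_isi_end:
            raise ValueError("min_ibi must be >= max_isi_end")


def _candidates(times: np.ndarray, start_isi: float, end_isi: float):
    """Phase 1: candidate (first_index, last_index) pairs, inclusive."""
    n = times.size
    if n < 2:
        return []
    isi = np.diff(times)
    if start_isi == end_isi:
        # vectorised maximal runs of ISI <= threshold
        ok = isi <= start_isi
        if not ok.any():
            return []
        edges = np.diff(ok.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if ok[0]:
            starts = np.r_[0, starts]
        if ok[-1]:
            ends = np.r_[ends, isi.size]
        return [(int(i), int(j)) for i, j in zip(starts, ends)]
    out = []
    i = 0
    while i < n - 1:
        if isi[i] <= start_isi:
            j = i + 1
            while j < n - 1 and isi[j] <= end_isi:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> list[Burst]:
    """Max-interval burst detection (detect -> merge -> filter)."""
    params = params or BurstParams()
    times = train.times
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    cands = _candidates(times, params.max_isi_start, params.max_isi_end)
    if not cands:
        return []
    # phase 2: merge candidates with gaps < min_ibi (absorbing spikes between)
    merged: list[list[int]] = [list(cands[0])]
    for i, j in cands[1:]:
        prev = merged[-1]
        if times[i] - times[prev[1]] < params.min_ibi:
            prev[1] = j
        else:
            merged.append([i, j])
    # phase 3: filter on duration and spike count (spikes counted inclusively
    # over the merged interval, which may absorb lone spikes between cores)
    out: list[Burst] = []
    for i, j in merged:
        t0, t1 = times[i], times[j]
        n = int(np.searchsorted(times, t1, side="right")
                - np.searchsorted(times, t0, side="left"))
        if t1 - t0 >= params.min_duration and n >= params.min_spikes:
            out.append(Burst(t_start=float(t0), t_end=float(t1), n_spikes=n,
                             electrode=train.meta.electrode))
    return out


def detect_network_bursts(bursts_by_electrode: dict[int, list[Burst]],
                          min_electrodes: int = 3,
                          resolution: float = 0.001,
                          min_ibi: float = 0.100,
                          trains: dict[int, SpikeTrain] | None = None,
                          ) -> list[NetworkBurst]:
    """Detect network bursts from per-electrode burst lists of one well.

    The burst-occupancy count (number of electrodes currently inside a burst,
    with burst intervals treated as half-open ``[t_start, t_end)`` quantised
    to ``resolution``) is swept over time; each maximal interval with count
    >= ``min_electrodes`` is a network burst.  Network bursts separated by
    less than ``min_ibi`` are merged.  If ``trains`` is given the spike count
    inside each network interval is filled in, otherwise it is the number of
    burst spikes whose bursts overlap the interval clipped to it.
    """
    # work on the integer resolution grid to keep boundary comparisons exact
    events = []  # (grid index, delta)
    for elec, blist in bursts_by_electrode.items():
        if not (1 <= int(elec) <= 12):
            raise ValueError(f"electrode id {elec} outside 1-12")
        for b in blist:
            k0 = round(b.t_start / resolution)
            k1 = round(b.t_end / resolution)
            if k1 > k0:
                events.append((k0, 1))
                events.append((k1, -1))
    if not events:
        return []
    # ends (-1) processed before starts (+1) at equal times: half-open intervals
    events.sort(key=lambda e: (e[0], e[1]))
    intervals: list[tuple[int, int]] = []
    count = 0
    k_open: int | None = None
    for k, d in events:
        count += d
        if k_open is None and count >= min_electrodes:
            k_open = k
        elif k_open is not None and count < min_electrodes:
            intervals.append((k_open, k))
            k_open = None
    # merge close network bursts
    gap = round(min_ibi / resolution)
    merged: list[list[int]] = []
    for k0, k1 in intervals:
        if merged and k0 - merged[-1][1] < gap:
            merged[-1][1] = k1
        else:
            merged.append([k0, k1])
    out = []
    for k0, k1 in merged:
        t0, t1 = k0 * resolution, k1 * resolution
        elecs = set()
        n_sp = 0
        for elec, blist in bursts_by_electrode.items():
            for b in blist:
                if b.t_start < t1 and b.t_end > t0:
                    elecs.add(int(elec))
        if trains is not None:
            for elec in elecs:
                tr = trains.get(elec)
                if tr is not None:
                    n_sp += int(np.searchsorted(tr.times, t1)
                                - np.searchsorted(tr.times, t0))
        else:
            for elec, blist in bursts_by_electrode.items():
                for b in blist:
                    if b.t_start < t1 and b.t_end > t0:
                        frac_lo = max(t0, b.t_start)
                        frac_hi = min(t1, b.t_end)
                        if b.duration > 0:
                            n_sp += int(round(b.n_spikes * (frac_hi - frac_lo)
                                              / b.duration))
                        else:
                            n_sp += b.n_spikes
        out.append(NetworkBurst(t_start=float(t0), t_end=float(t1),
                                electrodes=frozenset(elecs), n_spikes=n_sp))
    return out
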