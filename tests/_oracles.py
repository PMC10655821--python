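"""Independent reference implementations used to cross-check the package.

These are deliberately plain, slow, list-based translations of the
definitions, kept free of the vectorised code paths they validate.
"""

import numpy as np


def bursts_bruteforce(times, max_isi_start=0.050, max_isi_end=0.050,
                      min_ibi=0.100, min_duration=0.050, min_spikes=4):
    """Three-phase max-interval burst detection, reference version.

    Returns a list of (first_spike_time, last_spike_time, n_spikes).
    """
    times = list(times)
    n = len(times)
    # phase 1: detect candidate cores
    cores = []
    i = 0
    while i < n - 1:
        if times[i + 1] - times[i] <= max_isi_start:
            j = i + 1
            while j < n - 1 and times[j + 1] - times[j] <= max_isi_end:
                j += 1
            cores.append([i, j])
            i = j + 1
        else:
            i += 1
    # phase 2: merge cores separated by less than min_ibi
    merged = []
    for c in cores:
        if merged and times[c[0]] - times[merged[-1][1]] < min_ibi:
            merged[-1][1] = c[1]
        else:
            merged.append(list(c))
    # phase 3: filter on duration and (inclusive) spike count
    out = []
    for i, j in merged:
        t0, t1 = times[i], times[j]
        count = sum(1 for t in times if t0 <= t <= t1)
        if t1 - t0 >= min_duration and count >= min_spikes:
            out.append((t0, t1, count))
    return out


def network_bursts_grid(bursts_by_electrode, min_electrodes=3,
                        resolution=0.001, min_ibi=0.100):
    """Network bursts via explicit 1-ms time-grid occupancy counting.

    Burst intervals are quantised to the grid and treated as half-open.
    Returns a list of (t_start, t_end) as integer grid indices.
    """
    ivs = []
    for elec, blist in bursts_by_electrode.items():
        for b in blist:
            k0 = round(b.t_start / resolution)
            k1 = round(b.t_end / resolution)
            if k1 > k0:
                ivs.append((k0, k1))
    if not ivs:
        return []
    kmax = max(k1 for _, k1 in ivs) + 2
    occ = np.zeros(kmax, dtype=int)
    for k0, k1 in ivs:
        occ[k0:k1] += 1
    ok = occ >= min_electrodes
    # maximal runs of grid cells with occupancy >= threshold
    runs = []
    k = 0
    while k < kmax:
        if ok[k]:
            j = k
            while j + 1 < kmax and ok[j + 1]:
                j += 1
            runs.append([k, j + 1])
            k = j + 1
        else:
            k += 1
    gap = round(min_ibi / resolution)
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < gap:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    return [(a, b) for a, b in merged]
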