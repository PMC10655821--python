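"""Ground-truth-annotated synthetic MEA plates and proportion datasets.

The generator emulates a developing two-genotype culture on a multi-well MEA
plate: per electrode, a tonic homogeneous Poisson spike process is superposed
with burst events (regular trains at the profile's intra-burst ISI), a
fraction of electrodes are "silent" (all rates scaled by 0.02), and
well-level *network events* keep at least three electrodes simultaneously in
burst for the profile's network-burst duration by tiling the event interval
with standard-length bursts on three relay tracks.

Independent (non-network) bursts are placed with two constraints that make
the generated activity map one-to-one onto detector output: a minimum gap of
150 ms between bursts on one electrode (larger than the 100 ms burst-merge
parameter), and cross-electrode avoidance so that at most two electrodes are
ever in an independent burst simultaneously (chance >= 3 coincidences would
otherwise be detected as spurious network bursts).

Everything is driven by a single :class:`numpy.random.Generator`; the same
seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RecordingMeta, SpikeTrain, VoltageRecording
from .profiles import (CultureProfile, MIN_BURST_GAP, NETWORK_JITTER,
                       SILENT_SCALE, _network_shares, effective_tracks,
                       make_profile, n_spikes_in_burst, tile_schedule,
                       tracks_requested)

__all__ = [
    "PlateSpec",
    "GroundTruth",
    "WellTruth",
    "ZibSimSpec",
    "simulate_spike_trains",
    "simulate_well",
    "render_voltage",
    "simulate_zib_dataset",
    "spike_template",
    "draw_amplitudes",
]

#: default spike-amplitude distribution: Normal(60, 10^2) µV truncated at 25
AMP_MEAN, AMP_SD, AMP_FLOOR = 60.0, 10.0, 25.0
#: default noise level of rendered traces (µV)
DEFAULT_NOISE_SD = 8.0


@dataclass(frozen=True)
class PlateSpec:
    """Plate geometry and recording schedule."""

    n_wells: int = 24
    electrodes_per_well: int = 12
    recording_duration: float = 300.0
    sampling_rate: float = 20000.0
    divs: tuple = (tuple(range(4, 43)))

    def __post_init__(self) -> None:
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        if self.n_wells < 1 or self.electrodes_per_well < 1:
            raise ValueError("plate must have wells and electrodes")
        object.__setattr__(self, "divs", tuple(self.divs))


@dataclass
class WellTruth:
    """Ground truth for one well on one recording day."""

    well: int
    div: int
    silent: np.ndarray                       # bool per electrode (0-based)
    network_events: list                     # (t0, t1, tuple-of-electrode-ids)
    bursts: dict                             # elec id -> list[(t0, t1, kind)]
    spike_labels: dict                       # elec id -> array of label codes

    @property
    def n_nonsilent(self) -> int:
        return int((~self.silent).sum())


@dataclass
class GroundTruth:
    """Per-plate generation record plus the profile for closed-form truths."""

    profile: CultureProfile
    plate: PlateSpec
    wells: dict = field(default_factory=dict)   # (well, div) -> WellTruth

    def expected(self, div: float, duration: float | None = None) -> dict:
        from .profiles import expected_features
        return expected_features(
            self.profile, div, n_electrodes=self.plate.electrodes_per_well,
            duration=duration or self.plate.recording_duration)


def draw_amplitudes(rng: np.random.Generator, n: int, mean: float = AMP_MEAN,
                    sd: float = AMP_SD, floor: float = AMP_FLOOR) -> np.ndarray:
    """Truncated-normal spike amplitudes (µV, strictly positive)."""
    amps = rng.normal(mean, sd, n)
    bad = amps < floor
    while bad.any():
        amps[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = amps < floor
    return amps


def _gap_ok(t0: float, t1: float, intervals: list, gap: float) -> bool:
    """True if [t0, t1] keeps >= gap distance from every interval."""
    for a, b in intervals:
        if t0 < b + gap and t1 > a - gap:
            return False
    return True


def _overlap_count(t0: float, t1: float, intervals: list) -> int:
    return sum(1 for a, b in intervals if t0 < b and t1 > a)


def simulate_well(profile: CultureProfile, div: int, rng: np.random.Generator,
                  n_electrodes: int = 12, duration: float = 300.0,
                  well: int = 0, batch: str = "b1",
                  start_time: float = 0.0) -> tuple[list[SpikeTrain], WellTruth]:
    """Simulate the spike trains of one well on one day."""
    p = profile.at(div)
    if duration <= start_time:
        raise ValueError("duration must exceed start_time")
    isi = p["intra_burst_isi"]
    L = p["burst_duration"]
    E = p["network_burst_duration"]
    s_burst = n_spikes_in_burst(L, isi) if L > 0 else 0
    span_b = (s_burst - 1) * isi if s_burst else 0.0
    s_event = n_spikes_in_burst(E, isi) if E > 0 else 0
    span_e = (s_event - 1) * isi if s_event else 0.0
    t_lo, t_hi = start_time, duration

    silent = rng.random(n_electrodes) >= p["active_electrode_prob"]
    nonsilent = np.flatnonzero(~silent)
    n_ns = nonsilent.size

    # electrode id -> list of (t0, t1) occupied burst intervals (id is 1-based)
    occupied: dict[int, list] = {e + 1: [] for e in range(n_electrodes)}
    bursts: dict[int, list] = {e + 1: [] for e in range(n_electrodes)}
    spike_chunks: dict[int, list] = {e + 1: [] for e in range(n_electrodes)}
    label_chunks: dict[int, list] = {e + 1: [] for e in range(n_electrodes)}

    def add_burst(elec: int, t0: float, n_sp: int, kind: str) -> None:
        t1 = t0 + (n_sp - 1) * isi
        occupied[elec].append((t0, t1))
        bursts[elec].append((t0, t1, kind))
        spike_chunks[elec].append(t0 + np.arange(n_sp) * isi)
        label_chunks[elec].append(np.full(n_sp, kind))

    # --- network events -----------------------------------------------------
    events: list[tuple[float, float, tuple]] = []
    nbr = p["network_burst_rate"]
    if nbr > 0 and E > 0 and n_ns >= 3 and t_hi - t_lo > E:
        n_ev = rng.poisson(nbr / 60.0 * (t_hi - t_lo))
        # exact-count placement: distribute the free time between events as
        # Dirichlet gaps, so no event is lost to rejection even at high duty
        block = E + 2 * MIN_BURST_GAP
        n_ev = min(n_ev, int((t_hi - t_lo) / block))
        placed: list[tuple[float, float]] = []
        if n_ev > 0:
            slack = (t_hi - t_lo) - n_ev * block
            gaps = rng.dirichlet(np.ones(n_ev + 1)) * slack
            t = t_lo
            for g in gaps[:-1]:
                t += g
                placed.append((t, t + E))
                t += block
        n_req = tracks_requested(p["network_participation"], n_electrodes)
        for ev0, ev1 in placed:
            perm = rng.permutation(nonsilent) + 1  # electrode ids
            eff = effective_tracks(n_ns, E, L, isi, n_req) if L > 0 else 0
            if eff >= 3:
                starts, _span = tile_schedule(E, L, isi)
                tiles = sorted(starts * eff)
                used = set()
                for k, s in enumerate(tiles):
                    elec = int(perm[k % n_ns])
                    jit = rng.uniform(-NETWORK_JITTER, NETWORK_JITTER)
                    add_burst(elec, ev0 + max(0.0, s + jit), s_burst, "network")
                    used.add(elec)
                events.append((ev0, ev1, tuple(sorted(used))))
            else:
                used = tuple(int(e) for e in perm[:3])
                for elec in used:
                    jit = rng.uniform(-NETWORK_JITTER, NETWORK_JITTER)
                    add_burst(int(elec), ev0 + max(0.0, jit), s_event, "network")
                events.append((ev0, ev1, tuple(sorted(used))))

    # --- independent bursts (count-preserving placement with avoidance) -----
    nu_t, nu_f, *_ = _network_shares(p, n_electrodes)
    beta_ind = max(0.0, p["burst_rate"] - nbr * (nu_t + nu_f))
    indep_all: list[tuple[float, float]] = []      # all electrodes, for avoidance
    indep_by_elec: dict[int, list] = {}
    if beta_ind > 0 and s_burst >= 1 and t_hi - t_lo > span_b:
        for e in range(n_electrodes):
            elec = e + 1
            scale = SILENT_SCALE if silent[e] else 1.0
            n_b = rng.poisson(scale * beta_ind / 60.0 * (t_hi - t_lo))
            mine: list[tuple[float, float]] = []
            for _ in range(n_b):
                for _try in range(200):
                    u = rng.uniform(t_lo, t_hi - span_b)
                    cand = (u, u + span_b)
                    if not _gap_ok(*cand, occupied[elec], MIN_BURST_GAP):
                        continue
                    # strict cross-electrode avoidance: independent bursts
                    # never overlap anywhere in the well, so >=3-electrode
                    # coincidences can only come from network events
                    if _overlap_count(*cand, indep_all) == 0:
                        add_burst(elec, u, s_burst, "burst")
                        mine.append(cand)
                        indep_all.append(cand)
                        break
            indep_by_elec[elec] = mine

    # --- tonic spikes -------------------------------------------------------
    trains: list[SpikeTrain] = []
    labels: dict[int, np.ndarray] = {}
    for e in range(n_electrodes):
        elec = e + 1
        scale = SILENT_SCALE if silent[e] else 1.0
        n_t = rng.poisson(scale * p["tonic_rate"] * (t_hi - t_lo))
        tonic = rng.uniform(t_lo, t_hi, n_t)
        spike_chunks[elec].append(tonic)
        label_chunks[elec].append(np.full(n_t, "tonic"))
        times = np.concatenate(spike_chunks[elec]) if spike_chunks[elec] \
            else np.empty(0)
        labs = np.concatenate(label_chunks[elec]) if label_chunks[elec] \
            else np.empty(0, dtype=object)
        order = np.argsort(times, kind="stable")
        times, labs = times[order], labs[order]
        amps = draw_amplitudes(rng, times.size)
        meta = RecordingMeta(well=well, electrode=elec, div=div,
                             genotype=profile.genotype_label, batch=batch)
        trains.append(SpikeTrain(times=times, duration=duration,
                                 amplitudes=amps, meta=meta))
        labels[elec] = labs
        bursts[elec].sort()

    truth = WellTruth(well=well, div=div, silent=silent,
                      network_events=events, bursts=bursts,
                      spike_labels=labels)
    return trains, truth


def simulate_spike_trains(profile, plate: PlateSpec | None = None,
                          seed: int = 0, batch: str = "b1",
                          start_time: float = 0.0,
                          ) -> tuple[list[SpikeTrain], GroundTruth]:
    """Simulate every well and recording day of a plate.

    Returns the flat list of spike trains (one per electrode per well per
    DIV) and the :class:`GroundTruth` record.
    """
    profile = make_profile(profile)
    plate = plate or PlateSpec()
    rng = np.random.default_rng(seed)
    truth = GroundTruth(profile=profile, plate=plate)
    trains: list[SpikeTrain] = []
    for div in plate.divs:
        for w in range(plate.n_wells):
            tr, wt = simulate_well(
                profile, div, rng, n_electrodes=plate.electrodes_per_well,
                duration=plate.recording_duration, well=w, batch=batch,
                start_time=start_time)
            trains.extend(tr)
            truth.wells[(w, div)] = wt
    return trains, truth


# ---------------------------------------------------------------------------
# voltage rendering
# ---------------------------------------------------------------------------

def spike_template(sampling_rate: float, width: float = 0.0015
                   ) -> tuple[np.ndarray, int]:
    """Biphasic negative-leading template, peak-normalised to -1.

    Returns ``(template, peak_index)``; the template spans ``width`` seconds.
    """
    n = max(3, int(round(width * sampling_rate)))
    t = np.arange(n) / sampling_rate
    neg = np.exp(-0.5 * ((t - 0.00055) / 0.00012) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((t - 0.00105) / 0.00020) ** 2)
    w = pos - neg
    w /= abs(w.min())
    return w, int(np.argmin(w))


def render_voltage(trains, noise_sd: float = DEFAULT_NOISE_SD,
                   sampling_rate: float = 20000.0, seed: int = 0,
                   clean_baseline: bool = True, baseline_window: float = 1.0,
                   amp_mean: float = AMP_MEAN, amp_sd: float = AMP_SD,
                   amp_floor: float = AMP_FLOOR) -> list[VoltageRecording]:
    """Render spike trains into noisy extracellular voltage traces (µV).

    Gaussian noise of SD ``noise_sd`` plus one biphasic template per spike,
    scaled to the spike's amplitude with its negative peak at the spike time.
    With ``clean_baseline`` (default) spikes inside the first
    ``baseline_window`` seconds are not rendered, keeping the noise-estimation
    window of downstream detection uncontaminated; pass
    ``clean_baseline=False`` to render everything ("dirty baseline").
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if amp_floor <= 0:
        raise ValueError("amplitude distribution must be strictly positive")
    single = isinstance(trains, SpikeTrain)
    train_list = [trains] if single else list(trains)
    rng = np.random.default_rng(seed)
    tmpl, k0 = spike_template(sampling_rate)
    out = []
    for tr in train_list:
        n = int(round(tr.duration * sampling_rate))
        x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        amps = tr.amplitudes
        if amps is None:
            amps = draw_amplitudes(rng, tr.n_spikes, amp_mean, amp_sd, amp_floor)
        for t, a in zip(tr.times, amps):
            if clean_baseline and t < baseline_window:
                continue
            i0 = int(round(t * sampling_rate)) - k0
            j0, j1 = max(0, i0), min(n, i0 + tmpl.size)
            if j1 > j0:
                x[j0:j1] += a * tmpl[j0 - i0:j1 - i0]
        out.append(VoltageRecording(samples=x, sampling_rate=sampling_rate,
                                    meta=tr.meta))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# zero-inflated beta proportion data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZibSimSpec:
    """Simulation spec for bounded-proportion (puncta-area) data.

    The zero process is Bernoulli with logit-linear probability in centered
    DIV; positive responses are Beta(mu*phi, (1-mu)*phi) with logit(mu)
    linear in group, centered DIV, their interaction, and a batch random
    intercept.  Defaults emulate a three-batch, two-genotype assay recorded
    at DIV 14, 28 and 42.
    """

    n_batches: int = 3
    cells_per_batch_per_group: int = 500
    divs: tuple = (14, 28, 42)
    groups: tuple = ("cln3", "corrected")
    zero_coefs: tuple = (-1.2, 0.05)          # (intercept, per-DIV slope)
    mean_coefs: tuple = (-2.2, 0.3, 0.01, -0.02)  # (icpt, group, div, group:div)
    precision: float = 10.0
    batch_sd: float = 0.4
    div_center: float = 28.0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("precision phi must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_zib_dataset(spec: ZibSimSpec | None = None, seed: int = 0
                         ) -> pd.DataFrame:
    """Simulate a tidy proportion table (response, group, div, batch)."""
    spec = spec or ZibSimSpec()
    rng = np.random.default_rng(seed)
    b_int = rng.normal(0.0, spec.batch_sd, spec.n_batches)
    rows = []
    g0, g1 = spec.zero_coefs
    m0, mg, md, mgd = spec.mean_coefs
    for bi in range(spec.n_batches):
        for gi, group in enumerate(spec.groups):
            for div in spec.divs:
                n = spec.cells_per_batch_per_group
                dc = div - spec.div_center
                pi0 = _expit(g0 + g1 * dc)
                mu = _expit(m0 + mg * gi + md * dc + mgd * gi * dc + b_int[bi])
                zero = rng.random(n) < pi0
                y = np.zeros(n)
                pos = ~zero
                npos = int(pos.sum())
                a, b = mu * spec.precision, (1 - mu) * spec.precision
                draws = rng.beta(a, b, npos)
                bad = (draws >= 1.0) | (draws <= 0.0)
                while bad.any():
                    draws[bad] = rng.beta(a, b, int(bad.sum()))
                    bad = (draws >= 1.0) | (draws <= 0.0)
                y[pos] = draws
                rows.append(pd.DataFrame({
                    "response": y,
                    "group": group,
                    "div": div,
                    "batch": f"batch{bi + 1}",
                }))
    return pd.concat(rows, ignore_index=True)
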