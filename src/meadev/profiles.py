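"""Genotype activity profiles: piecewise-linear developmental trajectories.

A :class:`CultureProfile` stores, per anchor day-in-vitro (DIV), the
parameters of the generative activity model for one genotype:

``tonic_rate``              Hz      rate of the background Poisson spike process
``burst_rate``              /min    total per-electrode burst rate (independent
                                    bursts + network-event bursts)
``burst_duration``          s       duration of a single-electrode burst
``intra_burst_isi``         s       regular inter-spike interval inside bursts
``active_electrode_prob``   0-1     probability an electrode is not "silent"
``network_burst_rate``      /min    well-level rate of network events
``network_burst_duration``  s       duration of a network event (the interval
                                    over which >= 3 electrodes are kept in burst)
``network_participation``   0-1     minimum fraction of electrodes recruited

Values between anchors are linearly interpolated; outside the anchor range the
nearest anchor value is held (a single anchor therefore gives a constant
profile).  Two profiles ship with the package, ``"cln3"`` and ``"corrected"``,
whose trajectories are anchored to the developmental statistics of
patient-derived CLN3 and isogenic CRISPR-corrected cortical cultures
(spike rate peaks of 2.27 Hz at DIV 12 vs 15.02 Hz at DIV 25, etc.).

Network events are *tiled*: three relay "tracks" of standard-length bursts
cover the event interval so that at least three electrodes are continuously
in burst for the whole ``network_burst_duration``.  This is what allows the
network-burst duration to exceed the single-burst duration, as observed in
maturing cultures.  :func:`expected_features` evaluates the closed-form
expectation of every well-level feature implied by this generative model --
no simulation involved -- and is the ground truth against which pipeline
recovery is tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.stats import binom

__all__ = [
    "CultureProfile",
    "make_profile",
    "expected_features",
    "SHIPPED_PROFILES",
    "TILE_OVERLAP",
    "MIN_BURST_GAP",
    "n_spikes_in_burst",
    "tile_schedule",
    "effective_tracks",
    "tracks_requested",
]

FIELDS = (
    "tonic_rate",
    "burst_rate",
    "burst_duration",
    "intra_burst_isi",
    "active_electrode_prob",
    "network_burst_rate",
    "network_burst_duration",
    "network_participation",
)

SHIPPED_PROFILES = ("cln3", "corrected")

#: overlap between consecutive burst tiles in one relay track (s)
TILE_OVERLAP = 0.04
#: enforced minimum gap between any two bursts on one electrode (s)
MIN_BURST_GAP = 0.15
#: onset jitter applied to every network-event tile (s, uniform +/-)
NETWORK_JITTER = 0.01
#: rate multiplier applied to tonic/burst processes on silent electrodes
SILENT_SCALE = 0.02


@dataclass(frozen=True)
class CultureProfile:
    """Piecewise-linear genotype trajectory over DIV."""

    genotype_label: str
    divs: np.ndarray
    values: Mapping[str, np.ndarray]  # field -> per-anchor array

    def __post_init__(self) -> None:
        divs = np.asarray(self.divs, dtype=float)
        if divs.ndim != 1 or divs.size == 0:
            raise ValueError("anchor divs must be a non-empty 1-D sequence")
        if np.any(np.diff(divs) <= 0):
            raise ValueError("anchor divs must be strictly increasing")
        object.__setattr__(self, "divs", divs)
        vals = {}
        for name in FIELDS:
            if name not in self.values:
                raise ValueError(f"profile is missing field {name!r}")
            arr = np.asarray(self.values[name], dtype=float)
            if arr.shape != divs.shape:
                raise ValueError(f"field {name!r} length does not match divs")
            vals[name] = arr
        for name in ("tonic_rate", "burst_rate", "burst_duration",
                     "network_burst_rate", "network_burst_duration"):
            if np.any(vals[name] < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("active_electrode_prob", "network_participation"):
            if np.any((vals[name] < 0) | (vals[name] > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(vals["intra_burst_isi"] <= 0):
            raise ValueError("intra_burst_isi must be positive")
        object.__setattr__(self, "values", vals)

    def at(self, div: float) -> dict[str, float]:
        """Interpolated parameter set at one DIV (constant extrapolation)."""
        return {name: float(np.interp(div, self.divs, arr))
                for name, arr in self.values.items()}

    @property
    def div_range(self) -> tuple[float, float]:
        return float(self.divs[0]), float(self.divs[-1])


def _load_shipped(name: str) -> dict:
    ref = resources.files("meadev") / "profiles" / f"{name}.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def make_profile(name_or_table) -> CultureProfile:
    """Build a profile from a shipped id, a YAML-style mapping, or a path.

    ``make_profile("corrected")`` loads the shipped corrected-genotype
    trajectory; a mapping must provide ``genotype_label`` and an ``anchors``
    table with a ``div`` column plus one column per model field.
    """
    if isinstance(name_or_table, CultureProfile):
        return name_or_table
    if isinstance(name_or_table, str):
        if name_or_table in SHIPPED_PROFILES:
            table = _load_shipped(name_or_table)
        else:
            import os
            if os.path.exists(name_or_table):
                with open(name_or_table) as fh:
                    table = yaml.safe_load(fh)
            else:
                raise KeyError(
                    f"unknown profile {name_or_table!r}; shipped profiles are "
                    f"{SHIPPED_PROFILES}")
    else:
        table = name_or_table
    anchors = table["anchors"]
    divs = np.asarray(anchors["div"], dtype=float)
    values = {name: np.asarray(anchors[name], dtype=float) for name in FIELDS}
    return CultureProfile(genotype_label=table.get("genotype_label", "custom"),
                          divs=divs, values=values)


# ---------------------------------------------------------------------------
# closed-form expectations of the generative model
# ---------------------------------------------------------------------------

def n_spikes_in_burst(duration: float, isi: float) -> int:
    """Spike count of a regular burst: floor(duration/isi) + 1."""
    return int(math.floor(duration / isi + 1e-9)) + 1


#: tiles in consecutive groups must overlap by at least this much (s),
#: comfortably more than twice the onset jitter, so coverage has no gaps
COVER_MARGIN = 0.03


def tile_schedule(event_duration: float, burst_duration: float,
                  isi: float) -> tuple[list[float], float]:
    """Burst-group start offsets tiling a network event, and the burst span.

    A network event of duration ``E`` is covered by ``n_t`` groups of
    standard bursts (span = realised burst length, slightly under
    ``burst_duration``), evenly spaced from 0 to ``E - span`` so consecutive
    groups overlap by at least COVER_MARGIN.  Each group holds one burst per
    relay track, so >= 3 electrodes stay in burst over the whole event.
    """
    s = n_spikes_in_burst(burst_duration, isi)
    span = (s - 1) * isi
    E = event_duration
    if E <= span or span <= COVER_MARGIN:
        return [0.0], span
    n_t = int(math.ceil((E - span) / (span - COVER_MARGIN) - 1e-9)) + 1
    s_even = (E - span) / (n_t - 1)
    return [j * s_even for j in range(n_t)], span


def effective_tracks(n_avail: int, event_duration: float,
                     burst_duration: float, isi: float,
                     n_tracks: int) -> int:
    """Relay tracks a network event can sustain with ``n_avail`` electrodes.

    Tiles are assigned round-robin over the available electrodes in start
    order; an electrode must not receive two bursts closer than
    MIN_BURST_GAP (+ jitter margin).  Returns the largest feasible track
    count <= ``n_tracks``, or 0 when fewer than three tracks are
    sustainable (the event then falls back to three full-length bursts).
    """
    if n_avail < 3:
        return 0
    starts, span = tile_schedule(event_duration, burst_duration, isi)
    tr = min(int(n_tracks), n_avail)
    if len(starts) == 1:
        return tr if tr >= 3 else 0
    s_even = starts[1] - starts[0]
    need = span + MIN_BURST_GAP + 2 * NETWORK_JITTER + 0.02
    while tr >= 3 and (n_avail // tr) * s_even < need:
        tr -= 1
    return tr if tr >= 3 else 0


def tracks_requested(participation: float, n_electrodes: int = 12) -> int:
    """Relay-track count encoded by the network_participation field."""
    return max(3, int(round(participation * n_electrodes)))


def _network_shares(p: dict, n_electrodes: int
                    ) -> tuple[float, float, float, float, float]:
    """Expected per-(non-silent)-electrode network-burst shares.

    Returns ``(nu_tiled, nu_fallback, p_event, p_tiled, p_fallback)``:
    ``nu_tiled`` is the expected number of tile bursts a non-silent electrode
    receives per network event, ``nu_fallback`` the expected number of
    full-length fallback bursts (used when too few electrodes are available
    for round-robin tiling), ``p_event`` the probability a network event can
    run at all (>= 3 non-silent electrodes in the well), and ``p_tiled`` /
    ``p_fallback`` the well-level probabilities of each event form.
    """
    L = p["burst_duration"]
    E = p["network_burst_duration"]
    isi = p["intra_burst_isi"]
    if p["network_burst_rate"] <= 0 or E <= 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    n_per_track = len(tile_schedule(E, L, isi)[0])
    n_req = tracks_requested(p["network_participation"], n_electrodes)
    a = p["active_electrode_prob"]
    # our electrode is non-silent; the other 11 are iid Bernoulli(a)
    nu_t = nu_f = 0.0
    p_ev = p_tl = 0.0
    for others in range(n_electrodes):
        n = others + 1
        q = binom.pmf(others, n_electrodes - 1, a)
        q_well = binom.pmf(n, n_electrodes, a)
        if n < 3:
            continue
        p_ev += q_well
        eff = effective_tracks(n, E, L, isi, n_req)
        if eff >= 3:
            nu_t += q * eff * n_per_track / n
            p_tl += q_well
        else:
            nu_f += q * 3.0 / n
    return nu_t, nu_f, float(p_ev), float(p_tl), float(p_ev - p_tl)


def expected_features(profile: CultureProfile, div: float,
                      n_electrodes: int = 12,
                      duration: float = 300.0) -> dict[str, float]:
    """Analytic expectation of each well-level feature at one DIV.

    These are the generator's ground-truth values: rates follow from the
    Poisson superposition, burst spike counts from the regular intra-burst
    train, and network contributions from the exact binomial expectation over
    the number of non-silent electrodes.  ``mean_isi`` uses the point-process
    identity  E[mean ISI] ~= 1 / total rate;  ``mean_ibi`` the analogous
    gap expectation  60/burst_rate - mean burst duration.
    """
    p = profile.at(div)
    isi = p["intra_burst_isi"]
    L = p["burst_duration"]
    E = p["network_burst_duration"]
    s_burst = n_spikes_in_burst(L, isi) if L > 0 else 0
    span_b = (s_burst - 1) * isi if s_burst else 0.0   # realised burst span
    s_event = n_spikes_in_burst(E, isi) if E > 0 else 0
    span_e = (s_event - 1) * isi if s_event else 0.0

    nu_t, nu_f, p_ev, p_tl, p_fb = _network_shares(p, n_electrodes)
    nbr = p["network_burst_rate"]
    nu_tiled = nbr * nu_t          # /min, tile bursts per non-silent electrode
    nu_fall = nbr * nu_f           # /min, fallback full-length bursts
    nu = nu_tiled + nu_fall
    beta_ind = max(0.0, p["burst_rate"] - nu)
    burst_rate = beta_ind + nu

    burst_spike_rate = (beta_ind * s_burst + nu_tiled * s_burst
                        + nu_fall * s_event) / 60.0
    spike_rate = p["tonic_rate"] + burst_spike_rate

    if burst_rate > 0:
        mean_bd = ((beta_ind + nu_tiled) * span_b + nu_fall * span_e) \
            / burst_rate
        mean_ibi = max(0.0, 60.0 / burst_rate - mean_bd)
    else:
        mean_bd = math.nan
        mean_ibi = math.nan

    # detected network-burst duration: tiled events keep >=3 electrodes in
    # burst over [0, E]; fallback events over the full-length burst span
    if p_ev > 0:
        nbd = (p_tl * max(span_b, E) + p_fb * span_e) / p_ev
    else:
        nbd = math.nan

    return {
        "pct_active_electrodes": 100.0 * p["active_electrode_prob"],
        "spike_rate": spike_rate,
        "mean_isi": (1.0 / spike_rate) if spike_rate > 0 else math.nan,
        "burst_rate": burst_rate,
        "burst_duration": mean_bd if burst_rate > 0 else math.nan,
        "pct_spikes_in_bursts": (100.0 * burst_spike_rate / spike_rate
                                 if spike_rate > 0 else math.nan),
        "mean_ibi": mean_ibi,
        "network_burst_rate": nbr * p_ev,
        "network_burst_duration": nbd if nbr * p_ev > 0 else math.nan,
        "tonic_rate": p["tonic_rate"],
        "independent_burst_rate": beta_ind,
    }
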