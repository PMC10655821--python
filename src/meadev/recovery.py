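"""Parameter-recovery benchmark: simulate shipped profiles, run the full
pipeline, and measure the developmental statistics it recovers.

Each function regenerates synthetic plates from one of the shipped genotype
profiles (whose ground-truth trajectories are anchored to the printed
developmental statistics of CLN3 vs corrected cortical cultures), pushes
them through spike/burst/network-burst detection and well averaging, and
returns the recovered quantity together with the number of well-day
observations it is based on.  Spike-rate recovery for the early CLN3 window
goes through full voltage rendering and adaptive-threshold detection; the
other quantities are recovered at the spike-train level (detection from
voltage and direct spike-train input are equivalent up to detector recall,
which has its own dedicated checks).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import BurstParams, detect_bursts, detect_network_bursts
from .detection import DetectionParams, detect_spikes, electrode_is_active
from .features import phase_mean, well_average
from .profiles import make_profile
from .synthetic import render_voltage, simulate_well

__all__ = ["feature_table", "recover_all"]


def _seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), salt])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def feature_table(profile_name: str, divs, seed: int, n_wells: int = 8,
                  n_seeds: int = 5, duration: float = 300.0,
                  salt: int = 0) -> pd.DataFrame:
    """Well-feature table for repeated simulations of one profile.

    One row per active well per DIV per replicate seed, produced by the
    spike-train-level pipeline (burst detection, network-burst detection,
    well averaging over active electrodes).
    """
    profile = make_profile(profile_name)
    params = BurstParams()
    rows = []
    for rep, s in enumerate(_seeds(seed, n_seeds, salt)):
        rng = np.random.default_rng(s)
        for div in divs:
            for w in range(n_wells):
                trains, _ = simulate_well(profile, div, rng, well=w,
                                          duration=duration)
                bursts = {tr.meta.electrode: detect_bursts(tr, params)
                          for tr in trains}
                nb = detect_network_bursts(
                    bursts, trains={tr.meta.electrode: tr for tr in trains})
                wa = well_average(trains, bursts, nb)
                if wa is not None:
                    wa["replicate"] = rep
                    rows.append(wa)
    return pd.DataFrame(rows)


def peak_pct_active(seed: int, profile_name: str = "corrected",
                    div: int = 37, n_wells: int = 24, n_seeds: int = 5
                    ) -> tuple[float, int]:
    """Mean percentage of active electrodes at one DIV over whole plates."""
    profile = make_profile(profile_name)
    n_active = n_total = 0
    for s in _seeds(seed, n_seeds, 1):
        rng = np.random.default_rng(s)
        for w in range(n_wells):
            trains, _ = simulate_well(profile, div, rng, well=w)
            n_active += sum(electrode_is_active(tr) for tr in trains)
            n_total += len(trains)
    return 100.0 * n_active / n_total, n_total


def early_spike_rate_from_voltage(seed: int, profile_name: str = "cln3",
                                  divs=range(4, 11), n_wells: int = 4,
                                  n_seeds: int = 5, duration: float = 60.0
                                  ) -> tuple[float, int]:
    """Phase-mean well spike rate recovered through voltage rendering and
    adaptive-threshold detection (60-s traces at 20 kHz, 8 µV noise)."""
    profile = make_profile(profile_name)
    det = DetectionParams()
    bp = BurstParams()
    rows = []
    for s in _seeds(seed, n_seeds, 3):
        rng = np.random.default_rng(s)
        for div in divs:
            for w in range(n_wells):
                trains, _ = simulate_well(profile, div, rng, well=w,
                                          duration=duration,
                                          start_time=det.baseline_window)
                recs = render_voltage(trains, seed=int(rng.integers(2**31 - 1)))
                detected = [detect_spikes(r, det) for r in recs]
                bursts = {tr.meta.electrode: detect_bursts(tr, bp)
                          for tr in detected}
                nb = detect_network_bursts(
                    bursts, trains={t.meta.electrode: t for t in detected})
                wa = well_average(detected, bursts, nb)
                if wa is not None:
                    rows.append(wa)
    df = pd.DataFrame(rows)
    return phase_mean(df, "spike_rate", (min(divs), max(divs))), len(df)


def recover_all(seed: int = 1) -> dict[str, dict[str, float]]:
    """Run the whole recovery benchmark; returns quantity -> value/n."""
    out: dict[str, dict[str, float]] = {}

    def put(name, value, n):
        out[name] = {"value": float(value), "n": int(n)}

    v, n = peak_pct_active(seed)
    put("corrected_pct_active_div37", v, n)

    cln_early = feature_table("cln3", range(4, 13), seed, salt=2)
    put("cln3_pct_active_div4_8",
        phase_mean(cln_early, "pct_active_electrodes", (4, 8)), len(cln_early))
    put("cln3_burst_rate_div4_12",
        phase_mean(cln_early, "burst_rate", (4, 12)), len(cln_early))

    v, n = early_spike_rate_from_voltage(seed)
    put("cln3_spike_rate_div4_10_voltage", v, n)

    cor = feature_table("corrected", range(9, 43), seed, salt=4)
    put("corrected_spike_rate_div12_42",
        phase_mean(cor, "spike_rate", (12, 42)), len(cor))
    put("corrected_mean_isi_div17",
        phase_mean(cor, "mean_isi", (17, 17)), len(cor))
    put("corrected_burst_duration_div11_42",
        phase_mean(cor, "burst_duration", (11, 42)), len(cor))
    put("corrected_pct_spikes_in_bursts_div19",
        phase_mean(cor, "pct_spikes_in_bursts", (19, 19)), len(cor))
    put("corrected_network_burst_rate_div15",
        phase_mean(cor, "network_burst_rate", (15, 15)), len(cor))
    put("corrected_network_burst_duration_div9_42",
        phase_mean(cor, "network_burst_duration", (9, 42)), len(cor))
    return out
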