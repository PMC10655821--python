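"""Per-electrode MEA features, well averages, and DIV-phase summaries.

Nine features are carried per well per day: percentage of active electrodes,
spike rate (Hz), mean inter-spike interval (s), burst rate (/min), mean burst
duration (s), percentage of spikes in bursts, mean inter-burst interval (s),
network-burst rate (/min) and mean network-burst duration (s).

Per-electrode features are averaged over *active* electrodes only to give the
"well average", the unit of all downstream statistics; network features are
well-level quantities and are not re-averaged.  Features whose defining
events are absent (e.g. mean IBI with fewer than two bursts) are missing
(NaN), not zero -- with the exception of pct_spikes_in_bursts, which is a
true 0 when spikes exist but none fall in a burst.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bursts import Burst
from .core import NetworkBurst, SpikeTrain
from .detection import DetectionParams, electrode_is_active

__all__ = [
    "WELL_FEATURES",
    "electrode_features",
    "well_average",
    "phase_mean",
]

WELL_FEATURES = (
    "pct_active_electrodes",
    "spike_rate",
    "mean_isi",
    "burst_rate",
    "burst_duration",
    "pct_spikes_in_bursts",
    "mean_ibi",
    "network_burst_rate",
    "network_burst_duration",
)

_ELECTRODE_FEATURES = ("spike_rate", "mean_isi", "burst_rate",
                       "burst_duration", "pct_spikes_in_bursts", "mean_ibi")


def electrode_features(train: SpikeTrain, bursts: Sequence[Burst],
                       params: DetectionParams | None = None) -> dict[str, float]:
    """Feature record for one electrode on one recording day.

    spike_rate is the mean over 1-s bins of the bin spike counts (Hz);
    mean_isi uses all consecutive spike pairs; burst spike membership is
    inclusive of the boundary spikes.
    """
    params = params or DetectionParams()
    t = train.times
    n = t.size
    out: dict[str, float] = {}

    bin_w = params.rate_bin
    n_bins = max(1, int(np.floor(train.duration / bin_w + 1e-9)))
    in_range = int(np.searchsorted(t, n_bins * bin_w, side="left"))
    out["spike_rate"] = in_range / (n_bins * bin_w)

    out["mean_isi"] = float(np.diff(t).mean()) if n >= 2 else np.nan

    out["burst_rate"] = len(bursts) * 60.0 / train.duration
    if bursts:
        out["burst_duration"] = float(np.mean([b.duration for b in bursts]))
        in_burst = 0
        for b in bursts:
            in_burst += int(np.searchsorted(t, b.t_end, side="right")
                            - np.searchsorted(t, b.t_start, side="left"))
        out["pct_spikes_in_bursts"] = 100.0 * in_burst / n if n else np.nan
        if len(bursts) >= 2:
            starts = np.array([b.t_start for b in bursts])
            ends = np.array([b.t_end for b in bursts])
            out["mean_ibi"] = float(np.mean(starts[1:] - ends[:-1]))
        else:
            out["mean_ibi"] = np.nan
    else:
        out["burst_duration"] = np.nan
        out["pct_spikes_in_bursts"] = 0.0 if n else np.nan
        out["mean_ibi"] = np.nan
    return out


def well_average(trains: Sequence[SpikeTrain],
                 bursts_by_electrode: dict[int, Sequence[Burst]],
                 network_bursts: Sequence[NetworkBurst],
                 params: DetectionParams | None = None,
                 n_electrodes: int = 12) -> dict[str, float] | None:
    """Average per-electrode features over active electrodes of one well.

    Returns ``None`` for an inactive well (no active electrode): such wells
    are excluded from analysis.  NaN electrode values are ignored feature by
    feature (an active electrode without bursts contributes no burst
    duration but still contributes its spike rate).
    """
    if not trains:
        raise ValueError("no electrodes supplied")
    params = params or DetectionParams()
    active = [tr for tr in trains if electrode_is_active(tr)]
    if not active:
        return None
    records = [electrode_features(tr, list(bursts_by_electrode.get(
        tr.meta.electrode, ())), params) for tr in active]
    out: dict[str, float] = {}
    for name in _ELECTRODE_FEATURES:
        vals = np.array([r[name] for r in records], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = float(np.nanmean(vals))
    out["pct_active_electrodes"] = 100.0 * len(active) / n_electrodes
    duration = active[0].duration
    out["network_burst_rate"] = len(network_bursts) * 60.0 / duration
    out["network_burst_duration"] = (
        float(np.mean([nb.duration for nb in network_bursts]))
        if network_bursts else np.nan)
    meta = active[0].meta
    out.update(well=meta.well, div=meta.div, genotype=meta.genotype,
               batch=meta.batch)
    return out


def phase_mean(features: pd.DataFrame, feature: str,
               div_range: tuple[float, float],
               genotype: str | None = None) -> float:
    """Mean of per-well daily values of one feature over a DIV window.

    ``div_range`` is inclusive on both ends.  An empty selection yields NaN
    with a warning.
    """
    if feature not in features.columns:
        raise KeyError(f"unknown feature {feature!r}")
    lo, hi = div_range
    sel = (features["div"] >= lo) & (features["div"] <= hi)
    if genotype is not None:
        sel &= features["genotype"] == genotype
    vals = features.loc[sel, feature].astype(float)
    vals = vals[np.isfinite(vals)]
    if vals.empty:
        warnings.warn(
            f"no {feature} values for genotype={genotype} in DIV "
            f"[{lo}, {hi}]", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(vals.mean())
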