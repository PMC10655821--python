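# meadev

Analysis of spontaneous neuronal activity on multi-well microelectrode
arrays (MEA), built for longitudinal in-vitro disease models — the shipped
configuration emulates patient-derived **CLN3** (juvenile neuronal ceroid
lipofuscinosis) cortical neurons and their CRISPR-corrected isogenic
control, recorded daily from day in vitro (DIV) 4 to 42 on 24-well plates
with 12 electrodes per well.

The package covers the full chain from raw extracellular voltage to
genotype-level statistics:

* **Spike detection** — per-electrode adaptive threshold at 5x the
  baseline-noise SD (first second of each trace), negative-going crossings,
  2 ms dead time.
* **Activity gating** — an electrode is active at >= 10 spikes/min with
  >= 20 µV spikes; wells without an active electrode are excluded.
* **Burst detection** — the max-interval method (50 ms start/extend ISI,
  100 ms minimum inter-burst interval, 50 ms minimum duration, >= 4
  spikes), phases detect -> merge -> filter.
* **Network bursts** — maximal intervals with >= 3 of 12 electrodes
  simultaneously in burst (1 ms sweep), merged below 100 ms.
* **Well features** — nine per-well-per-day quantities (% active
  electrodes, spike rate, mean ISI, burst rate/duration, % spikes in
  bursts, mean IBI, network-burst rate/duration), averaged over active
  electrodes.
* **Trajectory GAM** — gamma family, log link, per-genotype cubic
  regression splines with a shrinkage penalty, GCV-selected smoothing,
  pointwise 95% bands and a link-scale genotype contrast:
  `g(E[y]) = beta_0 + beta_g + f_g(DIV)`.
* **Zero-inflated beta regression** — for bounded assay proportions (DQ-BSA
  puncta area / cell area): logit zero process (optionally on DIV), beta
  positive part `Beta(mu*phi, (1-mu)*phi)` with `logit(mu)` linear in
  group x DIV and a batch random intercept (adaptive Gauss–Hermite), plus
  a likelihood-ratio test for time in the zero process.
* **Synthetic plates** — a generator with exact closed-form ground truth
  (tonic Poisson + regular bursts + tiled network events + silent
  electrodes + biphasic-template voltage rendering), whose two shipped
  genotype profiles are anchored to the published developmental statistics.

See `docs/methods.md` for the models, their assumptions and the numerical
choices.

## Worked example

Simulate both genotypes (8 wells each, DIV 4–42), run the pipeline, and
compare spike-rate trajectories:

```python
import numpy as np, pandas as pd
from meadev import (PlateSpec, simulate_spike_trains, detect_bursts,
                    detect_network_bursts, well_average, fit_gamma_gam,
                    genotype_difference, GamConfig)

rows = []
for profile in ("cln3", "corrected"):
    plate = PlateSpec(n_wells=8, divs=range(4, 43))
    trains, truth = simulate_spike_trains(profile, plate, seed=1)
    by_well = {}
    for tr in trains:
        by_well.setdefault((tr.meta.well, tr.meta.div), []).append(tr)
    for ts in by_well.values():
        bursts = {t.meta.electrode: detect_bursts(t) for t in ts}
        nbs = detect_network_bursts(bursts,
                                    trains={t.meta.electrode: t for t in ts})
        wa = well_average(ts, bursts, nbs)
        if wa:
            rows.append(wa)
features = pd.DataFrame(rows)

fit = fit_gamma_gam(features, "spike_rate", GamConfig())
pred = fit.predict(np.arange(4, 43))
diff = genotype_difference(fit, np.arange(5, 42))
```

which prints (via the obvious summaries):

```
615 active well-day records
cln3      fitted spike-rate curve peaks at DIV 23: 2.51 Hz (95% CI 2.41-2.62)
corrected fitted spike-rate curve peaks at DIV 36: 15.26 Hz (95% CI 14.61-15.94)
smoothing lambda=13.4 (GCV), edf=18.5; corrected > cln3 with 95% CI excluding 0 on 37/37 grid days
```

i.e. the corrected line fires an order of magnitude faster at maturity and
the genotype contrast is pointwise significant across development — the
disease line's hypoactivity is recovered from raw synthetic plates end to
end. The `meadev` command exposes the same stages
(`meadev simulate`, `meadev pipeline`, `meadev gam`, `meadev zib`).

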