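# Methods

`meadev` reconstructs, as a tested pipeline, the analysis of spontaneous
activity in developing neuronal cultures on multi-well microelectrode-array
(MEA) plates: 24 wells of 12 electrodes, one 5-minute recording per day in
vitro (DIV) from DIV 4 to 42, two genotypes (patient-derived CLN3 neurons
and their CRISPR-corrected isogenic control). Because the raw recordings of
the study it models are not public, the package ships a synthetic-plate
generator whose ground truth is anchored to the published developmental
statistics; every pipeline stage is validated by recovering that ground
truth.

## Detection pipeline

**Spike detection.** Each electrode's threshold is 5x the sample standard
deviation of the baseline noise in the first second of its trace (the
generator keeps that second free of spikes; a `robust_baseline` MAD option
exists for contaminated baselines). A spike is registered at each
negative-going crossing of the threshold; the spike time is the extremum
within a 2 ms dead time after the crossing, the amplitude is the absolute
extremum, and crossings inside the dead time are absorbed. Polarity is
negative-only by default (extracellular spikes are negative-leading); a
`both` mode exists. The dead time is a standard refractory assumption that
prevents double counting; it is the one detection constant not fixed by the
activity definitions.

**Activity rules.** An electrode is *active* when it fires >= 10 spikes/min
and at least one spike reaches 20 µV; the amplitude criterion gates the
electrode, not individual spikes. A well is active when >= 1 electrode is;
inactive wells are excluded from analysis (and the exclusion is logged).

**Burst detection** uses the max-interval method with the standard
multi-well parameters: max ISI to start and to extend a burst 50 ms,
minimum inter-burst interval 100 ms, minimum duration 50 ms, minimum 4
spikes. Phase order is detect -> merge -> filter; this order changes
results and is therefore fixed. Burst boundaries are first/last spike
times; intervals are half-open `[t_start, t_end)`.

**Network bursts** are maximal intervals during which >= 3 of the well's 12
electrodes are simultaneously inside a single-electrode burst, computed by
an exact event sweep on a 1 ms quantisation grid (integer grid arithmetic
keeps boundary comparisons exact); network bursts separated by < 100 ms are
merged. No separate minimum duration is imposed.

**Features.** Nine quantities per well per day: % active electrodes, spike
rate (mean over 1-s bins, Hz), mean ISI (all consecutive pairs), burst rate
(/min), mean burst duration (s), % spikes in bursts (inclusive boundary
membership; a true 0 when spikes exist without bursts), mean IBI
(end-to-next-start gaps), network-burst rate (/min) and mean network-burst
duration (s). Per-electrode features are averaged over *active* electrodes
to form the well average, the unit of all statistics; network features are
well-level and not re-averaged. Features whose defining events are absent
are missing (NaN), not zero.

## Synthetic plates

Per electrode and day, activity is a superposition of

* a homogeneous Poisson *tonic* process,
* *independent bursts*: regular trains at the intra-burst ISI (default
  20 ms) of the day's burst duration, arriving at the profile's rate, and
* *network events* at the well level.

Electrodes are independently *silent* with probability
`1 - active_electrode_prob`; silent electrodes have tonic and burst rates
scaled by 0.02 and are not recruited into network events.

**Network events are tiled, not same-onset.** The published network-burst
durations (seconds) exceed the single-burst durations (~1 s); under the
>= 3-overlap definition, simultaneous same-onset bursts could never produce
that, so a network event of duration `E` is covered by `n_tracks` relay
"tracks" of standard-length bursts whose evenly spaced groups overlap by
>= 30 ms, keeping `n_tracks >= 3` electrodes continuously in burst over
`[0, E]`. Tiles are assigned round-robin over a random permutation of the
non-silent electrodes with +/-10 ms onset jitter; the track count (encoded
in `network_participation`) is reduced automatically when too few
electrodes are available to respect the per-electrode burst gap, and an
event falls back to three full-length bursts (or is skipped below three
non-silent electrodes).

**Mapping generated bursts 1:1 onto detected bursts.** Bursts on one
electrode keep >= 150 ms gaps (above the 100 ms merge parameter), and
independent bursts are placed with *strict cross-electrode avoidance* — no
two independent bursts overlap anywhere in a well — so that >= 3-electrode
coincidences arise only from network events. Two further generator-level
consequences of the detector's definitions shape the shipped profiles:
tonic rates are kept <= ~2 Hz, because Poisson spiking above that rate
begins to satisfy the max-interval criteria by chance and creates spurious
short bursts; and the well-wide independent-burst occupancy is kept under
~0.35 electrode-fractions, because rejection packing of non-overlapping
intervals effectively excludes about twice the occupied fraction. Network
events are placed by exact-count Dirichlet gap allocation (no rejection
losses) with >= 300 ms separation.

Spike amplitudes are Normal(60, 10^2) µV truncated at 25 µV — comfortably
above the 20 µV activity criterion. Voltage rendering adds each spike as a
biphasic negative-leading template (1.5 ms width, negative peak scaled to
the spike amplitude at the spike time) in Gaussian noise of SD 8 µV at
20 kHz; the first second stays spike-free unless `clean_baseline=False`.

**Closed-form ground truth.** `expected_features` evaluates the exact
expectation of every well feature implied by the model — spikes per burst
`floor(L/isi) + 1`, realised burst span `(n-1)*isi`, network shares via the
exact binomial expectation over the number of non-silent electrodes
(including the fallback and skip regimes), mean ISI as 1/total rate, and
the probability a well contributes at all (used when calibrating pooled
phase means, since wells without network bursts or without active
electrodes drop out of the pooled average).

**Shipped profiles.** `cln3` and `corrected` store anchors at every integer
DIV 4–42, computed offline by inverting the closed-form model so that the
targeted phase means equal the published values exactly (e.g. corrected
peak spike rate 15.02 Hz at DIV 25, active-electrode peak 97.1% at DIV 37,
network-burst rate 3.09/min at DIV 15, in-burst spike fraction 88.69% at
DIV 19, mean ISI 0.21 s at DIV 17). The published statistics are not all
mutually consistent under any single stationary point-process model — the
printed mean ISI at a given DIV is not the reciprocal of the printed spike
rate there, and printed burst rates at the printed durations would saturate
the plate — so targeted quantities are honoured exactly and the remaining
trajectories are kept biologically plausible. Where the total spike rate
exceeds what tonic + independent bursts can carry under the constraints
above, the daily network-event rate is solved to absorb the remainder;
around the DIV-17 ISI anchor the network share is deliberately minimal (and
bursts short) so the well-average mean ISI concentrates, because that
estimator is sensitive to rare low-rate electrodes that pass the activity
bar with a single stray burst.

## Trajectory GAM

Each feature is modelled over DIV with a generalized additive model: gamma
family, log link, one cubic-regression-spline smooth per genotype plus a
genotype intercept. The basis (dimension k = 10) is parameterised by its
values at quantile-placed knots; the penalty is the integrated squared
second derivative plus a *shrinkage* term, 1e-3 times the projection onto
the penalty null space, so heavy smoothing collapses the smooth entirely.
Smooths carry sum-to-zero constraints absorbed by reparameterisation.

Fitting is penalized IRLS (for gamma/log the working weights are 1, so each
step is a penalized least-squares solve on `z = eta + (y - mu)/mu`). A
single smoothing parameter shared by both smooths is chosen by GCV on a
40-point log-spaced grid (1e-4 to 1e6); GCV differences below 0.5% are
treated as selection noise and the smoothest such model is taken (without
this Occam tie-break, near-constant responses can land on an arbitrary
point of an essentially flat GCV profile). Dispersion is the Pearson
estimate; intervals use the Bayesian covariance `phi (X'X + lam S)^{-1}`
with +/-1.96 sigma pointwise bands (no simultaneous correction). Genotype
trajectories are compared by the link-scale contrast with its delta-method
SE; DIVs where the 95% CI excludes zero are flagged. Extrapolation beyond
the fitted DIV range is refused. Zero feature values are treated as
missing for the gamma fit (the defining events were absent), with a
warning. The well, not the electrode, is the analysis unit; batch is not
modelled in the GAM.

## Zero-inflated beta regression

Per-cell puncta area normalised to cell area lies in [0, 1) with excess
zeros. The model is two-part: logit zero probability (intercept,
optionally + centered DIV) and, for positive values, a beta density in the
mean–precision parameterisation Beta(mu*phi, (1-mu)*phi) with
logit(mu) = intercept + group + centered DIV + interaction, plus an
optional Gaussian random intercept per culture batch in the mean model
only (three batches per line makes a one-dimensional random effect the
appropriate scope). The random effect is integrated by 9-node adaptive
Gauss–Hermite quadrature: per batch, a Newton search finds the mode of the
log integrand, the local curvature sets the node scale, and the quadrature
is applied on the shifted/scaled nodes (vectorised over batches).

Estimation is maximum likelihood via L-BFGS-B with phi and sigma_b on the
log scale, three random starts (plus optional warm starts — used when
fitting nested pairs for the likelihood-ratio test, so the alternative
never scores below the null for numerical reasons), an analytic gradient on
the no-random-effect path, and a -20 lower bound on the zero-model
intercept so datasets without zeros drive pi to ~0 instead of -infinity.
Standard errors are Wald, from a finite-difference observed-information
matrix; responses equal to exactly 1 are clipped to 1 - 1e-6 with a
warning. Whether the zero process depends on time is tested by a
likelihood-ratio test with a chi-square reference.

## Problem sizes and verification

The recovery benchmark simulates, per quantity, 5 replicate plates of 8
wells (24 wells for the active-electrode peak) at the spike-train level
over the relevant DIV window, and 4 wells x 7 DIVs x 5 replicates of 60-s
voltage traces at 20 kHz for the voltage-path spike-rate check; each
recovered phase mean must fall within 10% of the published value.
Component checks: burst detection agrees with a brute-force three-phase
enumeration on 1000 random trains; network-burst detection agrees with a
1-ms grid occupancy oracle on 200 random well configurations; noiseless
renderings are recovered with 100% recall at +/-1 sample and pure-noise
false positives stay under 0.1/s; the Gaussian/identity GAM matches a
ridge closed form to 1e-8, gamma curve recovery attains MAE < 0.1 on the
log scale at n = 600, and the null genotype comparison flags ~5% of grid
points over 200 replicates; the ZIB likelihood matches a direct textbook
evaluation to 1e-10, parameters are recovered within 2 SE at n = 4788, and
the LRT type-I error sits inside the binomial 95% band around 5% over 500
replicates.

## What the synthetic data does and does not emulate

The generator reproduces the *statistics the analysis consumes*: rates,
burst structure, synchrony, activity gating, amplitude and noise levels,
and their developmental trajectories. It does not emulate electrode drift,
local-field oscillations, multi-unit waveform overlap, spike-sorting
ambiguity, inter-electrode correlation outside network events (assumed
independent), or biological well-to-well heterogeneity beyond the silent-
electrode lottery. Passing recovery therefore shows the pipeline is
faithful to the stated definitions under realistic magnitudes — not that it
is robust to every artefact of real recordings. Known limitations: the
mean-ISI well average is heavy-tailed at low activity; GCV (rather than
REML) can undersmooth small noisy datasets; the ZIB random intercept enters
the mean model only; and the tiled network-event model is one of several
generative mechanisms compatible with the printed overlap statistics.
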