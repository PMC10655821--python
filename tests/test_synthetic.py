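"""Synthetic plate generator: spike trains, voltage rendering, proportions."""

import numpy as np
import pytest
from scipy import stats

from meadev.bursts import detect_bursts
from meadev.profiles import expected_features
from meadev.synthetic import (PlateSpec, ZibSimSpec, render_voltage,
                              simulate_spike_trains, simulate_well,
                              simulate_zib_dataset)

from test_profiles import single_anchor_profile

from conftest import make_train


class TestSimulateSpikeTrains:
    def test_zero_rates_give_empty_trains(self, rng):
        prof = single_anchor_profile(tonic_rate=0.0, burst_rate=0.0)
        trains, _ = simulate_well(prof, 20, rng)
        assert all(tr.n_spikes == 0 for tr in trains)

    def test_poisson_mean_count(self):
        # 2 Hz tonic for 300 s -> 600 spikes/electrode on average
        prof = single_anchor_profile(tonic_rate=2.0, burst_rate=0.0)
        rng = np.random.default_rng(7)
        counts = []
        for w in range(84):           # ~1000 electrodes
            trains, _ = simulate_well(prof, 20, rng, well=w)
            counts += [tr.n_spikes for tr in trains]
        grand = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(grand - 600.0) < 2 * se + 1e-9

    def test_burst_spike_count_by_construction(self, rng):
        # 0.5 s bursts at 20 ms intra-burst ISI contain floor(0.5/0.02)+1=26
        prof = single_anchor_profile(tonic_rate=0.0, burst_rate=6.0,
                                     burst_duration=0.5)
        trains, truth = simulate_well(prof, 20, rng)
        n_bursts = 0
        for tr in trains:
            for t0, t1, kind in truth.bursts[tr.meta.electrode]:
                n = int(np.sum((tr.times >= t0 - 1e-9)
                               & (tr.times <= t1 + 1e-9)))
                assert n == 26
                n_bursts += 1
        assert n_bursts > 0

    def test_min_gap_between_bursts(self, rng):
        prof = single_anchor_profile(burst_rate=20.0, burst_duration=0.2)
        _, truth = simulate_well(prof, 20, rng)
        for blist in truth.bursts.values():
            for (a0, a1, _), (b0, b1, _) in zip(blist, blist[1:]):
                assert b0 - a1 >= 0.15 - 1e-9

    def test_generated_bursts_map_one_to_one_to_detected(self, rng):
        prof = single_anchor_profile(tonic_rate=0.5, burst_rate=8.0,
                                     burst_duration=0.3)
        trains, truth = simulate_well(prof, 20, rng)
        for tr in trains:
            detected = detect_bursts(tr)
            assert len(detected) == len(truth.bursts[tr.meta.electrode])

    def test_network_bursts_recruit_at_least_three_electrodes(self, rng):
        prof = single_anchor_profile(tonic_rate=0.5, burst_rate=2.0,
                                     burst_duration=0.4,
                                     network_burst_rate=3.0,
                                     network_burst_duration=1.5,
                                     network_participation=0.5)
        _, truth = simulate_well(prof, 20, rng)
        assert truth.network_events
        for _, _, elecs in truth.network_events:
            assert len(elecs) >= 3

    def test_same_seed_bit_identical(self):
        prof = single_anchor_profile(network_burst_rate=2.0,
                                     network_burst_duration=1.0)
        plate = PlateSpec(n_wells=2, divs=(20,), recording_duration=60.0)
        a, _ = simulate_spike_trains(prof, plate, seed=42)
        b, _ = simulate_spike_trains(prof, plate, seed=42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.times, tb.times)
            assert np.array_equal(ta.amplitudes, tb.amplitudes)

    def test_rate_estimator_unbiased_over_seeds(self):
        # burst-free profile: detected-spike-rate estimator is unbiased
        prof = single_anchor_profile(tonic_rate=1.5, burst_rate=0.0)
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            trains, _ = simulate_well(prof, 20, rng)
            rates += [tr.rate for tr in trains]
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - 1.5) < 3 * se

    def test_closed_form_matches_simulation(self):
        prof = single_anchor_profile(tonic_rate=1.0, burst_rate=4.0,
                                     burst_duration=0.3,
                                     network_burst_rate=2.0,
                                     network_burst_duration=1.2,
                                     active_electrode_prob=0.9)
        truth = expected_features(prof, 20)
        rng = np.random.default_rng(3)
        rates, bursts = [], []
        for w in range(40):
            trains, wt = simulate_well(prof, 20, rng, well=w)
            for tr in trains:
                if not wt.silent[tr.meta.electrode - 1]:
                    rates.append(tr.rate)
                    bursts.append(len(wt.bursts[tr.meta.electrode]) / 5.0)
        assert np.mean(rates) == pytest.approx(truth["spike_rate"], rel=0.05)
        assert np.mean(bursts) == pytest.approx(truth["burst_rate"],
                                                rel=0.05)


class TestRenderVoltage:
    def test_noise_sd_of_empty_train(self):
        train = make_train([], duration=60.0)
        v = render_voltage(train, noise_sd=8.0, seed=3)
        assert np.std(v.samples) == pytest.approx(8.0, rel=0.02)

    def test_single_noiseless_spike_peak(self):
        train = make_train([2.0], duration=4.0, amplitudes=60.0)
        v = render_voltage(train, noise_sd=0.0, seed=0)
        assert v.samples.min() == pytest.approx(-60.0)
        assert np.argmin(v.samples) == int(round(2.0 * v.sampling_rate))

    def test_spikes_exceed_detection_threshold(self, rng):
        times = np.linspace(1.5, 58.0, 100)
        train = make_train(times, duration=60.0, amplitudes=60.0)
        v = render_voltage(train, noise_sd=8.0, seed=9)
        fs = v.sampling_rate
        for t in times:
            i = int(round(t * fs))
            assert v.samples[i - 10:i + 10].min() < -40.0

    def test_clean_baseline_by_default(self, rng):
        train = make_train([0.5, 2.0], duration=4.0, amplitudes=60.0)
        v = render_voltage(train, noise_sd=0.0, seed=0)
        assert np.all(v.samples[:int(1.0 * v.sampling_rate) - 40] >= -1e-9)
        dirty = render_voltage(train, noise_sd=0.0, seed=0,
                               clean_baseline=False)
        assert dirty.samples[:int(1.0 * v.sampling_rate)].min() < -50

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            render_voltage(make_train([], duration=1.0), noise_sd=-1.0)


class TestSimulateZib:
    def test_zero_fraction_at_logit_zero(self):
        spec = ZibSimSpec(zero_coefs=(0.0, 0.0), n_batches=1,
                          cells_per_batch_per_group=1700, divs=(28,))
        d = simulate_zib_dataset(spec, seed=4)
        frac = (d["response"] == 0).mean()
        se = np.sqrt(0.25 / len(d))
        assert abs(frac - 0.5) < 2 * se + 1e-9

    def test_uniform_case_is_beta_one_one(self):
        spec = ZibSimSpec(zero_coefs=(-30.0, 0.0), precision=2.0,
                          mean_coefs=(0.0, 0.0, 0.0, 0.0), batch_sd=0.0,
                          n_batches=1, cells_per_batch_per_group=2500,
                          divs=(28,))
        d = simulate_zib_dataset(spec, seed=5)
        y = d.loc[d["response"] > 0, "response"]
        assert len(y) >= 5000
        stat, _ = stats.kstest(y, "uniform")
        assert stat < 1.36 / np.sqrt(len(y))   # 5% critical value

    def test_batch_intercept_scale(self):
        spec = ZibSimSpec(batch_sd=0.5, n_batches=6,
                          cells_per_batch_per_group=2000, divs=(28,),
                          zero_coefs=(-30.0, 0.0),
                          mean_coefs=(0.0, 0.0, 0.0, 0.0))
        d = simulate_zib_dataset(spec, seed=11)
        logits = []
        for _, g in d.groupby("batch"):
            m = g.loc[g["response"] > 0, "response"].mean()
            logits.append(np.log(m / (1 - m)))
        sd = np.std(logits, ddof=1)
        assert 0.25 < sd < 0.75     # within 50% of the true 0.5

    def test_responses_inside_support(self):
        d = simulate_zib_dataset(ZibSimSpec(), seed=0)
        assert ((d["response"] >= 0) & (d["response"] < 1)).all()

    def test_invalid_precision_rejected(self):
        with pytest.raises(ValueError):
            ZibSimSpec(precision=0.0)
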