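"""Max-interval burst detection and network-burst detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bursts_bruteforce, network_bursts_grid
from meadev.bursts import BurstParams, detect_bursts, detect_network_bursts
from meadev.core import Burst

from conftest import make_train


class TestDetectBursts:
    @pytest.mark.parametrize("times_ms,expected", [
        # all five thresholds satisfied -> one burst of 4 spikes
        ([0, 40, 80, 120], [(0.0, 0.120, 4)]),
        # below the 4-spike minimum -> nothing
        ([0, 40, 80], []),
        # 90 ms gap < 100 ms min IBI -> merged into one 8-spike burst
        ([0, 40, 80, 120, 210, 250, 290, 330], [(0.0, 0.330, 8)]),
        # 140 ms gap -> two bursts
        ([0, 40, 80, 120, 260, 300, 340, 380],
         [(0.0, 0.120, 4), (0.260, 0.380, 4)]),
        ([], []),
    ])
    def test_printed_parameter_examples(self, times_ms, expected):
        train = make_train(np.asarray(times_ms) / 1000.0)
        got = [(b.t_start, b.t_end, b.n_spikes)
               for b in detect_bursts(train)]
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[0] == pytest.approx(e[0])
            assert g[1] == pytest.approx(e[1])
            assert g[2] == e[2]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            make_train([0.2, 0.1])

    @given(st.lists(st.integers(min_value=0, max_value=5000), min_size=0,
                    max_size=50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, ticks_ms):
        times = np.sort(np.unique(np.asarray(ticks_ms) / 1000.0 * 7.3 % 5.0))
        got = detect_bursts(make_train(times, duration=40.0))
        want = bursts_bruteforce(times)
        assert [(b.t_start, b.t_end, b.n_spikes) for b in got] == \
            pytest.approx([tuple(w) for w in want])

    @given(st.lists(st.floats(min_value=0, max_value=30, allow_nan=False),
                    min_size=0, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bursts_disjoint_with_min_gaps(self, raw):
        times = np.sort(np.unique(np.asarray(raw)))
        params = BurstParams()
        bursts = detect_bursts(make_train(times, duration=31.0), params)
        for a, b in zip(bursts, bursts[1:]):
            assert b.t_start - a.t_end >= params.min_ibi
        for b in bursts:
            assert b.n_spikes >= params.min_spikes
            assert b.duration >= params.min_duration


class TestDetectNetworkBursts:
    def _bursts(self, intervals_by_elec):
        return {e: [Burst(t_start=a, t_end=b, n_spikes=10, electrode=e)
                    for a, b in ivs]
                for e, ivs in intervals_by_elec.items()}

    def test_three_identical_bursts_form_one_network_burst(self):
        nb = detect_network_bursts(self._bursts({1: [(1.0, 1.5)],
                                                 2: [(1.0, 1.5)],
                                                 3: [(1.0, 1.5)]}))
        assert len(nb) == 1
        assert nb[0].t_start == pytest.approx(1.0)
        assert nb[0].t_end == pytest.approx(1.5)
        assert nb[0].electrodes == frozenset({1, 2, 3})

    def test_two_electrodes_are_below_threshold(self):
        nb = detect_network_bursts(self._bursts({1: [(0.0, 2.0)],
                                                 2: [(0.0, 2.0)]}))
        assert nb == []

    def test_partial_overlap_keeps_only_triple_interval(self):
        nb = detect_network_bursts(self._bursts({
            1: [(0.0, 1.0)], 2: [(0.5, 1.5)], 3: [(0.9, 1.2)]}))
        assert len(nb) == 1
        assert nb[0].t_start == pytest.approx(0.9)
        assert nb[0].t_end == pytest.approx(1.0)

    def test_bad_electrode_id_rejected(self):
        with pytest.raises(ValueError):
            detect_network_bursts(self._bursts({13: [(0.0, 1.0)]}))

    def test_permutation_invariance_in_electrode_labels(self, rng):
        ivs = {}
        for e in range(1, 9):
            starts = np.sort(rng.uniform(0, 20, 5))
            ivs[e] = [(s, s + rng.uniform(0.1, 1.0)) for s in starts]
        perm = {e: int(p) for e, p in
                zip(ivs, rng.permutation(list(ivs)))}
        base = detect_network_bursts(self._bursts(ivs))
        relabelled = detect_network_bursts(
            self._bursts({perm[e]: v for e, v in ivs.items()}))
        assert [(round(n.t_start, 9), round(n.t_end, 9)) for n in base] == \
            [(round(n.t_start, 9), round(n.t_end, 9)) for n in relabelled]
        for a, b in zip(base, relabelled):
            assert {perm[e] for e in a.electrodes} == set(b.electrodes)

    def test_matches_grid_occupancy_oracle(self, rng):
        for _ in range(50):
            ivs = {}
            for e in range(1, rng.integers(3, 13)):
                k = rng.integers(0, 6)
                starts = np.sort(np.round(rng.uniform(0, 10, k), 3))
                ivs[e] = [(float(s), float(s + round(rng.uniform(0.05, 2.0),
                                                     3)))
                          for s in starts]
            got = detect_network_bursts(self._bursts(ivs))
            want = network_bursts_grid(self._bursts(ivs))
            got_k = [(round(n.t_start / 0.001), round(n.t_end / 0.001))
                     for n in got]
            assert got_k == want
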