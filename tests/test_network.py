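"""Network-burst detection, rate profiles and peak alignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurodish import synth
from neurodish.burst import detect_bursts
from neurodish.core import Burst, NetworkBurst, SpikeTrainSet
from neurodish.network import (
    align_network_bursts,
    detect_network_bursts,
    network_metrics,
    rate_profile,
)


def _burst(ch, start, end, n=5):
    return Burst(channel_id=ch, start=start, end=end, n_spikes=n)


def overlap_cluster_oracle(flat_bursts):
    """Brute-force clustering of overlapping/touching burst intervals via
    transitive closure over the pairwise-overlap graph."""
    n = len(flat_bursts)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = flat_bursts[i], flat_bursts[j]
            adj[i][j] = a.start <= b.end and b.start <= a.end
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


class TestDetectNetworkBursts:
    def test_five_of_sixteen_simultaneous_channels_qualify(self):
        bursts = {ch: [_burst(ch, 1.0, 1.2)] for ch in range(5)}
        nbs = detect_network_bursts(bursts, n_eligible=16)
        assert len(nbs) == 1
        assert nbs[0].n_channels == 5

    def test_four_of_sixteen_channels_do_not_qualify(self):
        bursts = {ch: [_burst(ch, 1.0, 1.2)] for ch in range(4)}
        assert detect_network_bursts(bursts, n_eligible=16) == []

    def test_no_bursts_anywhere_gives_no_events(self):
        assert detect_network_bursts({ch: [] for ch in range(16)}, n_eligible=16) == []

    def test_event_extent_spans_member_bursts(self):
        bursts = {ch: [_burst(ch, 1.0 + 0.05 * ch, 1.3 + 0.05 * ch)]
                  for ch in range(6)}
        (nb,) = detect_network_bursts(bursts, n_eligible=16)
        assert nb.start == pytest.approx(1.0)
        assert nb.end == pytest.approx(1.3 + 0.25)

    def test_gap_larger_than_window_splits_clusters(self):
        early = {ch: [_burst(ch, 1.0, 1.1)] for ch in range(5)}
        late = {ch: [_burst(ch, 5.0, 5.1)] for ch in range(5)}
        bursts = {ch: early.get(ch, []) + late.get(ch, []) for ch in range(5)}
        nbs = detect_network_bursts(bursts, n_eligible=16, window=0.1)
        assert len(nbs) == 2

    @given(seed=st.integers(0, 200))
    def test_activity_on_under_30_percent_of_channels_never_qualifies(self, seed):
        rng = np.random.default_rng(seed)
        n_ch = int(rng.integers(1, 5))  # at most 4 of 16 channels
        bursts = {ch: [] for ch in range(16)}
        for ch in range(n_ch):
            for _ in range(int(rng.integers(1, 6))):
                s = float(rng.uniform(0, 50))
                bursts[ch].append(_burst(ch, s, s + rng.uniform(0.01, 0.5)))
        assert detect_network_bursts(bursts, n_eligible=16) == []

    @given(seed=st.integers(0, 100))
    def test_zero_window_reduces_to_overlap_clustering(self, seed):
        rng = np.random.default_rng(seed)
        flat = []
        for ch in range(4):
            for _ in range(int(rng.integers(0, 5))):
                s = float(rng.uniform(0, 10))
                flat.append(_burst(ch, s, s + float(rng.uniform(0.05, 1.0))))
        bursts = {ch: sorted((b for b in flat if b.channel_id == ch),
                             key=lambda b: b.start) for ch in range(4)}
        nbs = detect_network_bursts(bursts, n_eligible=4, window=0.0,
                                    min_fraction=1e-9)
        got = {(round(nb.start, 9), round(nb.end, 9)) for nb in nbs}
        expected = set()
        for comp in overlap_cluster_oracle(flat):
            members = [flat[i] for i in comp]
            expected.add((round(min(b.start for b in members), 9),
                          round(max(b.end for b in members), 9)))
        assert got == expected


class TestNetworkMetrics:
    def test_no_events_give_zero_rate(self):
        m = network_metrics([], 480.0)
        assert m.nbr == 0.0
        assert m.nb_duration_mean is None

    def test_44_events_in_8_minutes_is_5_5_per_minute(self):
        nbs = [NetworkBurst(start=float(k), end=float(k) + 0.2,
                            participating_channels={0}) for k in range(44)]
        assert network_metrics(nbs, 480.0).nbr == pytest.approx(5.5)

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            network_metrics([], 0.0)

    def test_planted_event_rate_recovered(self):
        trains, gt = synth.gen_network_bursting_trains(
            n_channels=16, participation_fraction=0.5, nb_rate=6.0,
            duration=300.0, seed=8)
        bursts = {ch: detect_bursts(t, 0.1, channel_id=ch)
                  for ch, t in trains.trains.items()}
        nbs = detect_network_bursts(bursts, n_eligible=16, trains=trains)
        planted_nbr = len(gt.planted_network_bursts) / 300.0 * 60.0
        got = network_metrics(nbs, 300.0).nbr
        assert abs(got - planted_nbr) / planted_nbr < 0.10


class TestRateProfile:
    def test_total_rate_times_bin_conserves_spike_count(self):
        trains = synth.gen_poisson_trains(8, 1.0, 30.0, seed=5)
        prof = rate_profile(trains)
        assert prof.rate.sum() * prof.bin_width == pytest.approx(
            trains.total_spikes())

    def test_uniform_train_gives_flat_profile(self):
        t = (np.arange(100) + 0.5) * 0.01
        trains = SpikeTrainSet(trains={0: t}, duration=1.0)
        prof = rate_profile(trains, bin_width=0.01)
        assert np.all(prof.rate == prof.rate[0])

    def test_profile_peaks_inside_planted_event(self):
        trains, gt = synth.gen_network_bursting_trains(
            n_channels=16, participation_fraction=1.0, nb_rate=2.0,
            duration=120.0, seed=9)
        prof = rate_profile(trains)
        t_peak = prof.bin_centers[np.argmax(prof.rate)]
        assert any(s - 0.01 <= t_peak <= e + 0.01
                   for s, e, _ in gt.planted_network_bursts)


class TestAlignment:
    def _simple_profile_and_event(self):
        trains, _ = synth.gen_network_bursting_trains(
            n_channels=16, participation_fraction=1.0, nb_rate=2.0,
            duration=120.0, seed=10)
        bursts = {ch: detect_bursts(t, 0.1, channel_id=ch)
                  for ch, t in trains.trains.items()}
        nbs = detect_network_bursts(bursts, n_eligible=16, trains=trains)
        return trains, nbs

    def test_single_event_mean_equals_itself(self):
        trains, nbs = self._simple_profile_and_event()
        prof = rate_profile(trains)
        aligned, mean, taxis = align_network_bursts(nbs[:1], prof)
        np.testing.assert_array_equal(aligned[0], mean)
        assert taxis[np.argmax(mean)] == pytest.approx(0.0, abs=prof.bin_width)

    def test_identical_events_align_with_zero_variance(self):
        # spike times off the 10-ms bin edges so binning is float-stable
        t_burst = np.arange(20) * 0.0047 + 0.003
        trains = SpikeTrainSet(
            trains={ch: np.sort(np.concatenate([10.0 + t_burst, 30.0 + t_burst]))
                    for ch in range(6)}, duration=60.0)
        bursts = {ch: detect_bursts(t, 0.1, channel_id=ch)
                  for ch, t in trains.trains.items()}
        nbs = detect_network_bursts(bursts, n_eligible=6, trains=trains)
        assert len(nbs) == 2
        aligned, _, _ = align_network_bursts(nbs, rate_profile(trains))
        assert np.allclose(aligned[0], aligned[1])

    def test_mean_curve_rises_faster_than_it_decays(self):
        trains, nbs = self._simple_profile_and_event()
        aligned, mean, taxis = align_network_bursts(nbs, rate_profile(trains))
        half = mean.max() / 2.0
        above = np.flatnonzero(mean >= half)
        rise = 0.0 - taxis[above[0]]
        decay = taxis[above[-1]] - 0.0
        assert rise < decay

    def test_empty_event_list_rejected(self):
        trains = synth.gen_poisson_trains(2, 1.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            align_network_bursts([], rate_profile(trains))
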