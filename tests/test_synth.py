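"""Generator correctness: determinism, planted ground truth, rate sanity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurodish import synth


class TestPoissonTrains:
    def test_zero_rate_gives_empty_trains(self):
        trains = synth.gen_poisson_trains(4, rate=0.0, duration=100.0, seed=0)
        assert all(t.size == 0 for t in trains.trains.values())

    def test_mean_count_matches_rate_times_duration(self):
        trains = synth.gen_poisson_trains(16, rate=0.2, duration=480.0, seed=42)
        counts = [t.size for t in trains.trains.values()]
        expected = 0.2 * 480
        se = np.sqrt(expected / 16)  # SE of the mean of 16 Poisson counts
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_same_seed_reproduces_identical_times(self):
        a = synth.gen_poisson_trains(4, 1.0, 60.0, seed=7)
        b = synth.gen_poisson_trains(4, 1.0, 60.0, seed=7)
        for ch in a.trains:
            np.testing.assert_array_equal(a.trains[ch], b.trains[ch])

    @pytest.mark.parametrize("rate,duration", [(-1.0, 10.0), (1.0, 0.0), (1.0, -5.0)])
    def test_invalid_arguments_raise(self, rate, duration):
        with pytest.raises(ValueError):
            synth.gen_poisson_trains(2, rate, duration, seed=0)

    @given(seed=st.integers(0, 10_000), rate=st.floats(0.0, 5.0))
    def test_times_strictly_increasing_and_in_range(self, seed, rate):
        trains = synth.gen_poisson_trains(2, rate, 30.0, seed=seed)
        for t in trains.trains.values():
            assert np.all(np.diff(t) > 0)
            assert t.size == 0 or (t[0] >= 0 and t[-1] <= 30.0)


class TestBurstingTrains:
    def test_zero_burst_rate_reduces_to_poisson(self):
        plain = synth.gen_poisson_trains(4, 0.5, 120.0, seed=3)
        bursty, gt = synth.gen_bursting_trains(
            4, background_rate=0.5, burst_rate=0.0, spikes_per_burst=5,
            intra_burst_isi=0.01, duration=120.0, seed=3)
        for ch in plain.trains:
            np.testing.assert_array_equal(plain.trains[ch], bursty.trains[ch])
        assert gt.planted_bursts == []

    def test_planted_burst_count_near_nominal_rate(self):
        _, gt = synth.gen_bursting_trains(
            16, background_rate=0.05, burst_rate=10.0, spikes_per_burst=8,
            intra_burst_isi=0.01, duration=480.0, seed=1)
        per_channel = np.bincount([b[0] for b in gt.planted_bursts], minlength=16)
        # Poisson with mean 80 per channel; mean over 16 channels
        assert abs(per_channel.mean() - 80) < 3 * np.sqrt(80 / 16)

    def test_every_planted_burst_contains_its_spikes(self):
        trains, gt = synth.gen_bursting_trains(
            4, background_rate=0.05, burst_rate=6.0, spikes_per_burst=6,
            intra_burst_isi=0.01, duration=200.0, seed=9)
        for ch, start, end, n in gt.planted_bursts:
            t = trains.trains[ch]
            inside = np.sum((t >= start) & (t <= end))
            assert inside >= n - 1  # coincident-spike dedup may drop at most a tie

    def test_ground_truth_bit_identical_across_calls(self):
        _, g1 = synth.gen_bursting_trains(2, 0.05, 5.0, 5, 0.01, 100.0, seed=11)
        _, g2 = synth.gen_bursting_trains(2, 0.05, 5.0, 5, 0.01, 100.0, seed=11)
        assert g1.planted_bursts == g2.planted_bursts

    def test_isi_separation_requirement_enforced(self):
        with pytest.raises(ValueError):
            synth.gen_bursting_trains(2, background_rate=1.0, burst_rate=5.0,
                                      spikes_per_burst=5, intra_burst_isi=0.2,
                                      duration=100.0, seed=0)


class TestNetworkBurstingTrains:
    def test_full_participation_recruits_every_channel(self):
        _, gt = synth.gen_network_bursting_trains(
            n_channels=8, participation_fraction=1.0, nb_rate=6.0,
            duration=120.0, seed=2)
        assert len(gt.planted_network_bursts) > 0
        for _, _, chans in gt.planted_network_bursts:
            assert len(chans) == 8

    def test_half_participation_recruits_rounded_subset(self):
        _, gt = synth.gen_network_bursting_trains(
            n_channels=16, participation_fraction=0.5, nb_rate=6.0,
            duration=120.0, seed=2)
        for _, _, chans in gt.planted_network_bursts:
            assert len(chans) == 8

    def test_zero_event_rate_plants_nothing(self):
        _, gt = synth.gen_network_bursting_trains(
            n_channels=8, participation_fraction=1.0, nb_rate=0.0,
            duration=60.0, seed=0)
        assert gt.planted_network_bursts == []

    def test_participation_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_network_bursting_trains(participation_fraction=1.5, seed=0)


class TestRawTrace:
    def test_noise_sd_matches_request(self):
        silent = synth.gen_poisson_trains(1, 0.0, 10.0, seed=0)
        rec, _ = synth.gen_raw_trace(silent, fs=12500.0, noise_sd=5.0, seed=1)
        assert abs(rec.samples.std() - 5.0) / 5.0 < 0.05

    def test_planted_spike_lands_on_expected_sample(self):
        from neurodish.core import SpikeTrainSet
        trains = SpikeTrainSet(trains={0: np.array([1.0])}, duration=2.0)
        rec, gt = synth.gen_raw_trace(trains, fs=12500.0, noise_sd=1.0,
                                      spike_amplitude_sd=10.0, seed=2)
        assert gt.planted_spike_indices[0][0] == 12500
        # the waveform's negative peak should dominate around that sample
        k = 12500
        assert rec.samples[0, k] < -5.0

    def test_spike_beyond_duration_raises(self):
        from neurodish.core import SpikeTrainSet
        trains = SpikeTrainSet(trains={0: np.array([5.0])}, duration=2.0)
        with pytest.raises(ValueError):
            synth.gen_raw_trace(trains, fs=12500.0, seed=0)

    def test_same_seed_identical_trace(self):
        trains = synth.gen_poisson_trains(2, 1.0, 5.0, seed=4)
        r1, _ = synth.gen_raw_trace(trains, seed=5)
        r2, _ = synth.gen_raw_trace(trains, seed=5)
        np.testing.assert_array_equal(r1.samples, r2.samples)


class TestPatchGenerators:
    def test_subthreshold_steps_plant_no_aps(self):
        _, gt = synth.gen_cc_sweeps(rheobase=60.0, seed=0)
        for step, times in gt.planted_ap_times.items():
            if step < 60.0:
                assert times.size == 0
            else:
                assert times.size >= 1

    def test_invalid_step_duration_raises(self):
        with pytest.raises(ValueError):
            synth.gen_cc_sweeps(step_dur=0.0, seed=0)

    def test_vc_planted_peak_is_density_times_capacitance(self):
        densities = np.zeros(19)
        densities[7] = -305.6  # the −30 mV step of −100..+80 by 10
        _, gt = synth.gen_vc_sweeps(capacitance=20.0,
                                    peak_inward_density=densities,
                                    steady_outward_density=np.zeros(19), seed=0)
        assert gt.planted_peak_inward_pa[-30.0] == pytest.approx(-6112.0)

    def test_vc_zero_densities_give_flat_plateau(self):
        fam, _ = synth.gen_vc_sweeps(capacitance=20.0,
                                     peak_inward_density=np.zeros(19),
                                     steady_outward_density=np.zeros(19),
                                     cap_transient_pa=0.0, noise_sd_pa=0.5, seed=1)
        assert np.abs(fam.sweeps).max() < 5.0

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_vc_sweeps(capacitance=0.0, seed=0)


class TestProbeTableGenerator:
    def test_no_excludable_probes_means_clean_table(self):
        from neurodish import snp_qc
        df, _ = synth.gen_probe_table(n_probes=50, n_sex=0, n_chr0=0, n_mt=0,
                                      n_pos0=0, n_missing=0, n_indel=0,
                                      n_dup_pairs=0, n_dup_triples=0, seed=0)
        _, counts = snp_qc.filter_probes(df)
        assert all(v == 0 for v in counts.values())

    def test_planted_counts_recorded(self):
        df, gt = synth.gen_probe_table(n_probes=100, n_sex=9, n_chr0=2, n_mt=3,
                                       n_pos0=4, n_missing=6, n_indel=8, seed=1)
        assert gt.planted_filter_counts == {
            "chromosome": 14, "position": 4, "missing": 6, "snp_type": 8}

    def test_duplicate_groups_marked_with_multiplicity(self):
        df, gt = synth.gen_probe_table(n_probes=100, n_dup_pairs=5,
                                       n_dup_triples=4, seed=2)
        sizes = sorted(gt.planted_duplicate_groups.values())
        assert sizes == [2] * 5 + [3] * 4
        vc = df["probe_id"].value_counts()
        for pid, mult in gt.planted_duplicate_groups.items():
            assert vc[pid] == mult
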