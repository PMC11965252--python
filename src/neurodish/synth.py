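"""Synthetic electrophysiology and genotyping data with planted ground truth.

Every generator takes an explicit ``seed`` and draws from its own
``numpy.random.Generator`` stream, so identical arguments always yield
bit-identical outputs and nothing touches global RNG state.  The generators
emulate the regimes seen in maturing glutamatergic cultures: Poisson
background firing, channel-level bursts riding on that background,
cross-channel synchronized network bursts with a steep-rise/slow-decay
population-rate envelope, extracellular spike waveforms on band-limited
noise, current-clamp AP trains above a planted rheobase, voltage-clamp
families with fast inward and sustained outward currents, and SNP-array
probe tables with planted excludable and duplicated probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .core import PatchSweepFamily, RawRecording, SpikeTrainSet

__all__ = [
    "GroundTruth",
    "gen_poisson_trains",
    "gen_bursting_trains",
    "gen_network_bursting_trains",
    "default_spike_waveform",
    "gen_raw_trace",
    "gen_cc_sweeps",
    "gen_vc_sweeps",
    "default_iv_densities",
    "gen_probe_table",
]


@dataclass
class GroundTruth:
    """Record of everything a generator planted, for recovery scoring."""

    rng_seed: Optional[int] = None
    planted_spike_times: Dict[object, np.ndarray] = field(default_factory=dict)
    # (channel, start_s, end_s, n_spikes)
    planted_bursts: List[Tuple[object, float, float, int]] = field(default_factory=list)
    merged_burst_collisions: int = 0
    # (start_s, end_s, participating_channels)
    planted_network_bursts: List[Tuple[float, float, frozenset]] = field(default_factory=list)
    planted_spike_indices: Dict[object, np.ndarray] = field(default_factory=dict)
    planted_rheobase: Optional[float] = None  # pA
    planted_ap_times: Dict[float, np.ndarray] = field(default_factory=dict)
    planted_threshold_mv: Optional[float] = None
    planted_peak_mv: Optional[float] = None
    planted_capacitance: Optional[float] = None  # pF
    planted_peak_inward_pa: Dict[float, float] = field(default_factory=dict)
    planted_steady_outward_pa: Dict[float, float] = field(default_factory=dict)
    planted_filter_counts: Dict[str, int] = field(default_factory=dict)
    planted_duplicate_groups: Dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------

def _poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """One homogeneous Poisson train on [0, duration)."""
    if rate == 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _dedupe_sorted(t: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Enforce strictly increasing times by dropping coincident spikes."""
    if t.size < 2:
        return t
    keep = np.concatenate(([True], np.diff(t) > eps))
    return t[keep]


def gen_poisson_trains(
    n_channels: int,
    rate: float,
    duration: float,
    seed: int,
    well_id: str = "well",
) -> SpikeTrainSet:
    """Homogeneous Poisson spike trains, one per channel.

    Emulates a pre-bursting culture in which all spiking is random: the
    expected spike count per channel is ``rate × duration``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    trains = {
        ch: _dedupe_sorted(_poisson_train(rng, rate, duration))
        for ch in range(n_channels)
    }
    return SpikeTrainSet(trains=trains, duration=duration, well_id=well_id)


def _merge_planted_bursts(
    bursts: List[Tuple[float, float, int]]
) -> Tuple[List[Tuple[float, float, int]], int]:
    """Merge overlapping planted bursts; count collisions."""
    if not bursts:
        return [], 0
    bursts = sorted(bursts)
    merged = [list(bursts[0])]
    collisions = 0
    for s, e, n in bursts[1:]:
        if s <= merged[-1][1]:
            collisions += 1
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += n
        else:
            merged.append([s, e, n])
    return [tuple(b) for b in merged], collisions


def gen_bursting_trains(
    n_channels: int,
    background_rate: float,
    burst_rate: float,
    spikes_per_burst: int,
    intra_burst_isi: float,
    duration: float,
    seed: int,
    isi_jitter: float = 0.0,
    well_id: str = "well",
) -> Tuple[SpikeTrainSet, GroundTruth]:
    """Independent bursting channels: bursts placed by a Poisson process of
    rate ``burst_rate`` (bursts/min) on each channel, each burst a run of
    ``spikes_per_burst`` spikes at ``intra_burst_isi`` spacing, superposed
    on Poisson background firing.

    The intra-burst ISI should be much shorter than the mean background ISI
    (≤ 1/20 is enforced) so the two ISI modes stay separable — the regime a
    log-ISI burst detector is built for.  Overlapping planted bursts are
    merged in the ground truth and counted once.
    """
    if spikes_per_burst < 1:
        raise ValueError("spikes_per_burst must be >= 1")
    if burst_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if background_rate > 0 and burst_rate > 0:
        if intra_burst_isi > (1.0 / background_rate) / 20.0:
            raise ValueError(
                "intra_burst_isi must be <= 1/20 of the mean background ISI "
                "for the ISI modes to be separable"
            )
    rng = np.random.default_rng(seed)
    gt = GroundTruth(rng_seed=seed)
    trains: Dict[object, np.ndarray] = {}
    burst_span = (spikes_per_burst - 1) * intra_burst_isi
    for ch in range(n_channels):
        background = _poisson_train(rng, background_rate, duration)
        onsets = _poisson_train(rng, burst_rate / 60.0, max(duration - burst_span, 0.0))
        planted: List[Tuple[float, float, int]] = []
        burst_spikes = []
        for t0 in onsets:
            offs = np.arange(spikes_per_burst) * intra_burst_isi
            if isi_jitter > 0 and spikes_per_burst > 1:
                offs = offs + np.concatenate(
                    ([0.0], rng.uniform(-isi_jitter, isi_jitter, spikes_per_burst - 1))
                )
                offs = np.sort(np.abs(offs))
            times = t0 + offs
            burst_spikes.append(times)
            planted.append((float(times[0]), float(times[-1]), spikes_per_burst))
        merged, collisions = _merge_planted_bursts(planted)
        gt.merged_burst_collisions += collisions
        gt.planted_bursts.extend((ch, s, e, n) for s, e, n in merged)
        all_spikes = np.sort(
            np.concatenate([background] + burst_spikes) if burst_spikes else background
        )
        trains[ch] = _dedupe_sorted(all_spikes)
        gt.planted_spike_times[ch] = trains[ch]
    return SpikeTrainSet(trains=trains, duration=duration, well_id=well_id), gt


def gen_network_bursting_trains(
    n_channels: int = 16,
    participation_fraction: float = 1.0,
    nb_rate: float = 6.0,
    duration: float = 120.0,
    seed: int = 0,
    onset_jitter: float = 0.02,
    spikes_per_burst: int = 10,
    rise_tau: float = 0.01,
    decay_tau: float = 0.1,
    background_rate: float = 0.02,
    well_id: str = "well",
) -> Tuple[SpikeTrainSet, GroundTruth]:
    """Synchronized network bursting: at each planted network event a random
    subset of ``round(participation_fraction × n_channels)`` channels fires a
    burst whose onset is jittered by at most ``onset_jitter`` seconds.

    Within each channel burst the spikes are spaced by the inverse of an
    alpha-like rate envelope with a fast rise (``rise_tau``) and a slow decay
    (``decay_tau``), so the pooled population rate shows the canonical
    steep-rise/slow-decay shape of culture network bursts.
    """
    if not 0.0 <= participation_fraction <= 1.0:
        raise ValueError("participation_fraction must be in [0, 1]")
    if duration <= 0 or nb_rate < 0:
        raise ValueError("duration must be > 0 and nb_rate >= 0")
    if rise_tau >= decay_tau:
        raise ValueError("need rise_tau < decay_tau for an asymmetric envelope")
    rng = np.random.default_rng(seed)
    gt = GroundTruth(rng_seed=seed)
    n_participants = int(round(participation_fraction * n_channels))

    # burst spike offsets follow the cumulative alpha-like envelope:
    # r(t) ∝ (1 − exp(−t/rise)) · exp(−t/decay); spikes at equal quantiles
    t_env = np.linspace(0.0, 5.0 * decay_tau, 500)
    env = (1.0 - np.exp(-t_env / rise_tau)) * np.exp(-t_env / decay_tau)
    cdf = np.cumsum(env)
    cdf /= cdf[-1]
    q = (np.arange(spikes_per_burst) + 0.5) / spikes_per_burst
    burst_offsets = np.interp(q, cdf, t_env)
    span = burst_offsets[-1] - burst_offsets[0]

    margin = span + onset_jitter + 0.1
    n_events = rng.poisson(nb_rate / 60.0 * max(duration - margin, 0.0))
    event_starts = np.sort(rng.uniform(0.0, max(duration - margin, 0.0), size=n_events))
    # keep planted events separated so ground-truth events are unambiguous
    if event_starts.size > 1:
        keep = np.concatenate(([True], np.diff(event_starts) > 2.0 * margin))
        event_starts = event_starts[keep]

    per_channel: Dict[object, List[np.ndarray]] = {ch: [] for ch in range(n_channels)}
    for t0 in event_starts:
        participants = rng.choice(n_channels, size=n_participants, replace=False)
        t_min, t_max = np.inf, -np.inf
        for ch in participants:
            jit = rng.uniform(0.0, onset_jitter)
            times = t0 + jit + burst_offsets
            per_channel[ch].append(times)
            t_min = min(t_min, times[0])
            t_max = max(t_max, times[-1])
        if n_participants > 0:
            gt.planted_network_bursts.append(
                (float(t_min), float(t_max), frozenset(int(c) for c in participants))
            )
    trains: Dict[object, np.ndarray] = {}
    for ch in range(n_channels):
        background = _poisson_train(rng, background_rate, duration)
        chunks = per_channel[ch] + [background]
        t = np.sort(np.concatenate(chunks))
        trains[ch] = _dedupe_sorted(t)
        gt.planted_spike_times[ch] = trains[ch]
    for s, e, chans in gt.planted_network_bursts:
        for ch in chans:
            gt.planted_bursts.append((ch, s, e, spikes_per_burst))
    return SpikeTrainSet(trains=trains, duration=duration, well_id=well_id), gt


# --------------------------------------------------------------------------
# raw extracellular traces
# --------------------------------------------------------------------------

def default_spike_waveform(
    fs: float, amplitude: float = 1.0, duration: float = 0.001
) -> np.ndarray:
    """Biphasic extracellular spike template, dominant negative phase.

    ``amplitude`` sets the depth of the negative peak (same units as the
    trace); total duration ~1 ms by default.
    """
    n = max(int(round(duration * fs)), 5)
    t = np.linspace(0.0, 1.0, n)
    # negative lobe in the first 60%, smaller positive rebound after
    wf = -np.sin(np.pi * np.clip(t / 0.6, 0, 1)) + 0.35 * np.sin(
        np.pi * np.clip((t - 0.6) / 0.4, 0, 1)
    )
    return amplitude * wf / np.abs(wf).max()


def gen_raw_trace(
    spike_trains: SpikeTrainSet,
    fs: float = 12500.0,
    noise_sd: float = 5.0,
    waveform: Optional[np.ndarray] = None,
    spike_amplitude_sd: float = 8.0,
    seed: int = 0,
) -> Tuple[RawRecording, GroundTruth]:
    """Render spike trains as a raw multichannel voltage trace.

    Band-limited (200–3000 Hz) Gaussian noise of standard deviation
    ``noise_sd`` µV, with the spike waveform added at each spike time rounded
    to the nearest sample.  The default waveform's negative peak is
    ``spike_amplitude_sd × noise_sd`` deep.  Ground truth records the
    sample-accurate planted spike indices per channel.
    """
    if fs <= 2 * 3000.0:
        raise ValueError("sampling rate must exceed twice the 3 kHz band edge")
    rng = np.random.default_rng(seed)
    n_samples = int(round(spike_trains.duration * fs))
    if waveform is None:
        waveform = default_spike_waveform(fs, amplitude=spike_amplitude_sd * noise_sd)
    waveform = np.asarray(waveform, dtype=float)
    peak_offset = int(np.argmin(waveform))  # planted time = negative peak

    sos = signal.butter(4, [200.0, 3000.0], btype="bandpass", fs=fs, output="sos")
    gt = GroundTruth(rng_seed=seed)
    chans = spike_trains.channel_ids
    samples = np.empty((len(chans), n_samples))
    for i, ch in enumerate(chans):
        white = rng.standard_normal(n_samples)
        noise = signal.sosfiltfilt(sos, white)
        noise *= noise_sd / noise.std()
        trace = noise
        idx = np.round(np.asarray(spike_trains.trains[ch]) * fs).astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= n_samples):
            raise ValueError("spike time beyond trace duration")
        for k in idx:
            a = k - peak_offset
            b = a + waveform.size
            lo, hi = max(a, 0), min(b, n_samples)
            trace[lo:hi] += waveform[lo - a : hi - a]
        samples[i] = trace
        gt.planted_spike_indices[ch] = idx
        gt.planted_spike_times[ch] = np.asarray(spike_trains.trains[ch])
    rec = RawRecording(
        samples=samples, fs=fs, channel_ids=chans, well_id=spike_trains.well_id
    )
    return rec, gt


# --------------------------------------------------------------------------
# patch-clamp sweep families
# --------------------------------------------------------------------------

def _ap_waveform(
    fs: float,
    threshold_mv: float,
    peak_mv: float,
    baseline_mv: float,
    width_ms: float = 2.0,
) -> Tuple[np.ndarray, int]:
    """Stereotyped AP shape: slow depolarization from baseline to threshold
    (dV/dt ~10 mV/ms, below typical detection criteria), fast rise from
    threshold to peak, repolarization with a small afterhyperpolarization.
    Returns (waveform relative to baseline, index of the peak sample)."""
    approach_dvdt = 10.0  # mV/ms, sub-criterion approach to threshold
    rise_ms = 0.35
    fall_ms = width_ms - rise_ms / 2.0
    ahp_ms = 3.0
    approach_ms = (threshold_mv - baseline_mv) / approach_dvdt
    n_appr = max(int(approach_ms * 1e-3 * fs), 2)
    n_rise = max(int(rise_ms * 1e-3 * fs), 2)
    n_fall = max(int(fall_ms * 1e-3 * fs), 2)
    n_ahp = max(int(ahp_ms * 1e-3 * fs), 2)
    appr = np.linspace(baseline_mv, threshold_mv, n_appr, endpoint=False)
    up = np.linspace(threshold_mv, peak_mv, n_rise)
    ahp_mv = baseline_mv - 5.0
    down = np.linspace(peak_mv, ahp_mv, n_fall)
    rec = ahp_mv + (baseline_mv - ahp_mv) * (1 - np.exp(-np.linspace(0, 5, n_ahp)))
    wf = np.concatenate([appr, up, down[1:], rec[1:]]) - baseline_mv
    return wf, n_appr + n_rise - 1


def gen_cc_sweeps(
    rheobase: float = 60.0,
    step_start: float = 0.0,
    step_delta: float = 10.0,
    step_max: float = 100.0,
    step_dur: float = 0.5,
    f_of_I: Optional[Union[Mapping[float, int], Callable[[float], int]]] = None,
    fs: float = 25000.0,
    capacitance: float = 20.0,
    resting_mv: float = -70.0,
    threshold_mv: float = -40.0,
    peak_mv: float = 30.0,
    ap_width_ms: float = 2.0,
    input_resistance_mohm: float = 150.0,
    membrane_tau: float = 0.02,
    noise_sd_mv: float = 0.2,
    pre_s: float = 0.1,
    post_s: float = 0.1,
    seed: int = 0,
) -> Tuple[PatchSweepFamily, GroundTruth]:
    """Current-clamp sweep family under a linear gradient of depolarizing
    current steps (default Δ = 10 pA, 500 ms, mirroring the standard
    protocol).

    Steps below the planted ``rheobase`` show only a subthreshold RC
    membrane response; steps at or above it contain stereotyped APs at the
    count given by ``f_of_I`` (a mapping or callable from step current in pA
    to AP count; default: one AP at rheobase plus one per additional 10 pA).
    Ground truth stores the rheobase and per-step AP peak times, threshold
    and peak voltages.
    """
    if step_delta <= 0:
        raise ValueError("step_delta must be positive")
    if step_dur <= 0:
        raise ValueError("step_dur must be positive")
    rng = np.random.default_rng(seed)
    steps = np.arange(step_start, step_max + 0.5 * step_delta, step_delta)
    if f_of_I is None:
        f_of_I = lambda i: 1 + int((i - rheobase) // 10.0) if i >= rheobase else 0
    n_of = (lambda i: int(f_of_I(i))) if callable(f_of_I) else (
        lambda i: int(f_of_I.get(i, 0))
    )
    n_pre = int(pre_s * fs)
    n_step = int(step_dur * fs)
    n_post = int(post_s * fs)
    n_total = n_pre + n_step + n_post
    wf, peak_idx = _ap_waveform(fs, threshold_mv, peak_mv, resting_mv, ap_width_ms)

    gt = GroundTruth(
        rng_seed=seed,
        planted_rheobase=float(rheobase),
        planted_threshold_mv=float(threshold_mv),
        planted_peak_mv=float(peak_mv),
        planted_capacitance=float(capacitance),
    )
    sweeps = np.empty((steps.size, n_total))
    t_step = np.arange(n_step) / fs
    for si, i_pa in enumerate(steps):
        v = np.full(n_total, resting_mv)
        # subthreshold RC charging toward resting + I·Rin, clipped near threshold
        v_inf = min(i_pa * input_resistance_mohm * 1e-3, threshold_mv - resting_mv + 5.0)
        v[n_pre : n_pre + n_step] += v_inf * (1.0 - np.exp(-t_step / membrane_tau))
        v[n_pre + n_step :] = resting_mv  # release
        n_aps = n_of(float(i_pa)) if i_pa >= rheobase else 0
        ap_times = np.empty(0)
        if n_aps > 0:
            # APs evenly spread across the step
            rel = (np.arange(n_aps) + 0.5) / n_aps * (step_dur - 0.02) + 0.01
            onset_idx = n_pre + np.round(rel * fs).astype(int)
            for k in onset_idx:
                a, b = k, min(k + wf.size, n_total)
                seg = wf[: b - a].copy()
                v[a:b] = resting_mv + seg  # AP overrides subthreshold response
            ap_times = (onset_idx + peak_idx) / fs
        sweeps[si] = v + rng.normal(0.0, noise_sd_mv, n_total)
        gt.planted_ap_times[float(i_pa)] = ap_times
    fam = PatchSweepFamily(
        mode="cc",
        sweeps=sweeps,
        fs=fs,
        step_values=steps,
        step_window=(pre_s, pre_s + step_dur),
        capacitance=capacitance,
        holding=resting_mv,
    )
    return fam, gt


def default_iv_densities(
    step_mv: np.ndarray,
    peak_inward: float = -305.6,
    peak_outward: float = 150.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Realistic per-step current-density profiles (pA/pF).

    Inward (Na⁺-like): activates above −50 mV, most negative around −30 mV,
    reverses near +60 mV.  Outward (delayed-rectifier-like): grows roughly
    linearly above −40 mV reaching ``peak_outward`` at +80 mV.
    """
    step_mv = np.asarray(step_mv, dtype=float)
    act = 1.0 / (1.0 + np.exp(-(step_mv + 38.0) / 6.0))
    driving = (step_mv - 60.0) / (-30.0 - 60.0)  # 1 at −30 mV, 0 at +60
    j_in = peak_inward * act * driving
    j_in = np.minimum(j_in, 0.0)
    # normalize so the planted value at −30 mV equals peak_inward exactly
    at30 = np.interp(-30.0, step_mv, j_in) if step_mv.size > 1 else j_in
    if np.any(np.isclose(step_mv, -30.0)) and at30 != 0:
        j_in *= peak_inward / j_in[np.argmin(np.abs(step_mv + 30.0))]
    j_out = peak_outward * np.clip((step_mv + 40.0) / 120.0, 0.0, None)
    return j_in, j_out


def gen_vc_sweeps(
    capacitance: float = 20.0,
    peak_inward_density: Optional[Sequence[float]] = None,
    steady_outward_density: Optional[Sequence[float]] = None,
    step_start_mv: float = -100.0,
    step_max_mv: float = 80.0,
    step_delta_mv: float = 10.0,
    step_dur: float = 0.5,
    holding_mv: float = -70.0,
    fs: float = 25000.0,
    inward_peak_delay_ms: float = 2.0,
    inward_tau_ms: float = 1.0,
    outward_tau_ms: float = 10.0,
    cap_transient_pa: float = 2000.0,
    noise_sd_pa: float = 5.0,
    pre_s: float = 0.05,
    post_s: float = 0.05,
    seed: int = 0,
) -> Tuple[PatchSweepFamily, GroundTruth]:
    """Voltage-clamp sweep family over steps −100 → +80 mV (Δ = 10 mV,
    500 ms, holding −70 mV by default).

    Each sweep carries a fast-inactivating inward transient (planted peak =
    inward density × capacitance, peaking ``inward_peak_delay_ms`` after step
    onset) plus a sustained outward plateau (density × capacitance), a brief
    capacitive transient at step onset, and Gaussian current noise.  Ground
    truth stores the planted per-step peak inward and steady outward currents.
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    rng = np.random.default_rng(seed)
    steps = np.arange(step_start_mv, step_max_mv + 0.5 * step_delta_mv, step_delta_mv)
    if peak_inward_density is None or steady_outward_density is None:
        j_in_def, j_out_def = default_iv_densities(steps)
        if peak_inward_density is None:
            peak_inward_density = j_in_def
        if steady_outward_density is None:
            steady_outward_density = j_out_def
    j_in = np.asarray(peak_inward_density, dtype=float)
    j_out = np.asarray(steady_outward_density, dtype=float)
    if j_in.size != steps.size or j_out.size != steps.size:
        raise ValueError("need one density per voltage step")

    n_pre = int(pre_s * fs)
    n_step = int(step_dur * fs)
    n_post = int(post_s * fs)
    n_total = n_pre + n_step + n_post
    t_step = np.arange(n_step) / fs

    gt = GroundTruth(rng_seed=seed, planted_capacitance=float(capacitance))
    sweeps = np.empty((steps.size, n_total))
    d = inward_peak_delay_ms * 1e-3
    tau_i = inward_tau_ms * 1e-3
    tau_o = outward_tau_ms * 1e-3
    # alpha-like kernel peaking exactly at t = d with unit amplitude
    kern = (t_step / d) * np.exp(1.0 - t_step / d)
    inact = np.exp(-np.clip(t_step - d, 0.0, None) / (5.0 * tau_i))
    inward_shape = kern * inact
    inward_shape /= inward_shape.max()
    outward_shape = 1.0 - np.exp(-t_step / tau_o)
    cap_shape = np.exp(-t_step / 0.0003)  # ~0.3 ms capacitive spike
    for si, v in enumerate(steps):
        i_in = min(j_in[si] * capacitance, 0.0)
        i_out = j_out[si] * capacitance
        base = i_out * outward_shape
        # scale the inward kernel so the planted *net* peak inward current —
        # what a voltage-clamp analysis actually measures — equals i_in
        # exactly despite overlap with the rising outward current
        amp = 0.0
        if i_in < 0.0:
            k = int(np.argmax(inward_shape))
            for _ in range(3):
                amp = (i_in - base[k]) / inward_shape[k]
                k = int(np.argmin(base + amp * inward_shape))
        tr = np.zeros(n_total)
        tr[n_pre : n_pre + n_step] = (
            base
            + amp * inward_shape
            + np.sign(v - holding_mv) * cap_transient_pa * cap_shape
        )
        sweeps[si] = tr + rng.normal(0.0, noise_sd_pa, n_total)
        gt.planted_peak_inward_pa[float(v)] = float(i_in)
        gt.planted_steady_outward_pa[float(v)] = float(i_out)
    fam = PatchSweepFamily(
        mode="vc",
        sweeps=sweeps,
        fs=fs,
        step_values=steps,
        step_window=(pre_s, pre_s + step_dur),
        capacitance=capacitance,
        holding=holding_mv,
    )
    return fam, gt


# --------------------------------------------------------------------------
# SNP-array probe tables
# --------------------------------------------------------------------------

def gen_probe_table(
    n_probes: int = 1000,
    n_sex: int = 30,
    n_chr0: int = 5,
    n_mt: int = 5,
    n_pos0: int = 10,
    n_missing: int = 10,
    n_indel: int = 10,
    n_dup_pairs: int = 20,
    n_dup_triples: int = 10,
    seed: int = 0,
    sample_id: str = "sample",
) -> Tuple[pd.DataFrame, GroundTruth]:
    """SNP-array probe table with planted excludable and duplicated probes.

    ``n_probes`` clean autosomal probes are augmented with planted probes
    that each fail exactly one exclusion filter (sex/0/MT chromosome,
    position 0, missing R or BAF, Indel/Deletion type) plus duplicated probe
    ids (pairs and triples).  Ground truth records the per-filter planted
    counts and which ids are duplicated how many times.
    """
    for v in (n_probes, n_sex, n_chr0, n_mt, n_pos0, n_missing, n_indel,
              n_dup_pairs, n_dup_triples):
        if v < 0:
            raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    autosomes = [str(c) for c in range(1, 23)]

    def _mk(n, chrom=None, pos=None, snp_type="SNP", missing=False, prefix="p"):
        rows = []
        for i in range(n):
            c = chrom if chrom is not None else rng.choice(autosomes)
            p = pos if pos is not None else int(rng.integers(1, 2_000_000_000))
            r = np.nan if missing and i % 2 == 0 else float(rng.lognormal(0.0, 0.25))
            baf = np.nan if missing and i % 2 == 1 else float(rng.uniform(0, 1))
            rows.append(
                {"probe_id": f"{prefix}{_mk.counter}", "chromosome": c,
                 "position": p, "snp_type": snp_type, "R": r, "BAF": baf,
                 "sample_id": sample_id}
            )
            _mk.counter += 1
        return rows

    _mk.counter = 0
    rows = _mk(n_probes)
    sex_labels = ["X", "Y", "XY"]
    sex_rows = []
    for i in range(n_sex):
        sex_rows += _mk(1, chrom=sex_labels[i % 3], prefix="sex")
    rows += sex_rows
    rows += _mk(n_chr0, chrom="0", prefix="chr0_")
    rows += _mk(n_mt, chrom="MT", prefix="mt")
    rows += _mk(n_pos0, pos=0, prefix="pos0_")
    rows += _mk(n_missing, missing=True, prefix="na")
    ind_rows = []
    for i in range(n_indel):
        ind_rows += _mk(1, snp_type="Indel" if i % 2 == 0 else "Deletion", prefix="ind")
    rows += ind_rows

    gt = GroundTruth(
        rng_seed=seed,
        planted_filter_counts={
            "chromosome": n_sex + n_chr0 + n_mt,
            "position": n_pos0,
            "missing": n_missing,
            "snp_type": n_indel,
        },
    )
    df = pd.DataFrame(rows)
    # duplicate clean probes: pairs get 1 extra copy, triples 2 extra
    clean_ids = [r["probe_id"] for r in rows[:n_probes]]
    dup_ids = rng.choice(clean_ids, size=n_dup_pairs + n_dup_triples, replace=False)
    extra = []
    for j, pid in enumerate(dup_ids):
        n_copies = 1 if j < n_dup_pairs else 2
        gt.planted_duplicate_groups[str(pid)] = n_copies + 1
        base = df[df.probe_id == pid].iloc[0].to_dict()
        for _ in range(n_copies):
            cp = dict(base)
            cp["R"] = float(rng.lognormal(0.0, 0.25))
            cp["BAF"] = float(rng.uniform(0, 1))
            extra.append(cp)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return df, gt
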