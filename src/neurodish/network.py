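"""Network-burst detection, network metrics, firing-rate profiles and
peak-aligned network-burst averaging.

A network burst is a cluster of near-simultaneous single-channel bursts:
bursts whose extents are separated by gaps of at most ``window`` (100 ms)
are chained, and the cluster qualifies as a network burst when it recruits
at least ``min_fraction`` (30%) of the eligible channels — with 16
electrodes per well this is ceil(0.3 × 16) = 5 distinct channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Burst, NetworkBurst, RateProfile, SpikeTrainSet

__all__ = [
    "detect_network_bursts",
    "network_metrics",
    "rate_profile",
    "align_network_bursts",
    "NetworkMetrics",
]


def detect_network_bursts(
    bursts: Dict[object, Sequence[Burst]],
    n_eligible: Optional[int] = None,
    window: float = 0.1,
    min_fraction: float = 0.30,
    trains: Optional[SpikeTrainSet] = None,
    bin_width: float = 0.010,
) -> List[NetworkBurst]:
    """Chain single-channel bursts into network bursts.

    Bursts from all channels are taken in start-time order and chained into
    a candidate cluster while the gap between the cluster's running end and
    the next burst's start is at most ``window`` (overlapping bursts have
    gap ≤ 0 and always chain).  A cluster becomes a network burst iff it
    recruits at least ``ceil(min_fraction × n_eligible)`` distinct channels.

    ``n_eligible`` defaults to the number of channels in ``bursts`` (pass 16
    to count against the full electrode array).  When ``trains`` is given,
    each event is annotated with the peak time and peak rate of the pooled
    10-ms firing-rate profile restricted to the event span (ties broken
    toward the earliest bin).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if window < 0:
        raise ValueError("window must be non-negative")
    if n_eligible is None:
        n_eligible = len(bursts)
    min_channels = math.ceil(min_fraction * n_eligible)
    flat = sorted(
        (b for blist in bursts.values() for b in blist), key=lambda b: (b.start, b.end)
    )
    clusters: List[List[Burst]] = []
    for b in flat:
        if clusters and b.start - max(x.end for x in clusters[-1]) <= window:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    events: List[NetworkBurst] = []
    profile = rate_profile(trains, bin_width) if trains is not None else None
    for cl in clusters:
        chans = {b.channel_id for b in cl}
        if len(chans) < min_channels:
            continue
        start = min(b.start for b in cl)
        end = max(b.end for b in cl)
        nb = NetworkBurst(start=start, end=end, participating_channels=chans)
        if profile is not None:
            _annotate_peak(nb, profile)
        events.append(nb)
    return events


def _annotate_peak(nb: NetworkBurst, profile: RateProfile) -> None:
    centers = profile.bin_centers
    mask = (centers >= nb.start - profile.bin_width) & (centers <= nb.end + profile.bin_width)
    if not mask.any():
        nb.peak_time, nb.peak_rate = nb.start, 0.0
        return
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmax(profile.rate[idx]))]  # argmax returns earliest tie
    nb.peak_time = float(centers[k])
    nb.peak_rate = float(profile.rate[k])


@dataclass
class NetworkMetrics:
    nbr: float  # network bursts per minute
    nb_duration_mean: Optional[float]  # s
    nb_duration_sd: Optional[float]  # s
    n_events: int


def network_metrics(nbs: Sequence[NetworkBurst], duration: float) -> NetworkMetrics:
    """NBR (network bursts/min) and duration statistics."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = len(nbs)
    durs = np.array([nb.duration for nb in nbs])
    return NetworkMetrics(
        nbr=n / duration * 60.0,
        nb_duration_mean=float(durs.mean()) if n else None,
        nb_duration_sd=float(durs.std(ddof=1)) if n > 1 else (0.0 if n == 1 else None),
        n_events=n,
    )


def rate_profile(trains: SpikeTrainSet, bin_width: float = 0.010) -> RateProfile:
    """Cumulative instantaneous firing-rate profile: spikes of all channels
    pooled into uniform bins (10 ms default) and scaled to spikes/s."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(int(np.ceil(trains.duration / bin_width)), 1)
    edges = trains.t0 + np.arange(n_bins + 1) * bin_width
    pooled = trains.pooled()
    counts, _ = np.histogram(pooled, bins=edges)
    # spikes that sit exactly on the final edge belong to the last bin
    if pooled.size:
        counts[-1] += int(np.sum(pooled == edges[-1]))
    return RateProfile(bin_edges=edges, rate=counts / bin_width)


def align_network_bursts(
    nbs: Sequence[NetworkBurst],
    profile: RateProfile,
    pre: float = 0.5,
    post: float = 2.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align each network burst's rate-profile segment on its peak.

    The reference is the peak of the longest-duration event; every event's
    segment is shifted so its own peak bin coincides with the reference peak
    bin, then cropped to a fixed [−pre, +post] window around the peak.
    Returns ``(aligned, mean_curve, time_axis)`` where ``aligned`` has one
    row per event, ``time_axis`` is in seconds relative to the peak, and
    bins outside the recording are zero-padded.
    """
    if not nbs:
        raise ValueError("need at least one network burst to align")
    bw = profile.bin_width
    for nb in nbs:
        if nb.peak_time is None:
            _annotate_peak(nb, profile)
    n_pre = int(round(pre / bw))
    n_post = int(round(post / bw))
    width = n_pre + n_post + 1
    aligned = np.zeros((len(nbs), width))
    centers = profile.bin_centers
    for i, nb in enumerate(nbs):
        k = int(np.argmin(np.abs(centers - nb.peak_time)))
        lo, hi = k - n_pre, k + n_post + 1
        src_lo, src_hi = max(lo, 0), min(hi, profile.rate.size)
        aligned[i, src_lo - lo : src_lo - lo + (src_hi - src_lo)] = profile.rate[src_lo:src_hi]
    time_axis = (np.arange(width) - n_pre) * bw
    return aligned, aligned.mean(axis=0), time_axis
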