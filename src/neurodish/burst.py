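"""logISI burst detection and single-channel activity metrics.

Burst detection follows the log-ISI histogram approach: the inter-spike
interval histogram of a bursting channel is bimodal on a logarithmic axis,
with an intra-burst mode at short ISIs and an inter-burst mode at long
ISIs.  The burst-defining ISI threshold is placed at the valley between the
two modes, accepted only when the valley is deep enough as measured by the
void parameter

    v = 1 − h(min) / sqrt(h(peak1) · h(peak2))

between the intra-burst peak and a subsequent peak.  Constants (histogram
resolution, intra-burst ISI cap, void acceptance, fallback cutoff) are
implementation choices, configurable on every entry point:

* 10 histogram bins per decade of ISI,
* intra-burst peak searched at ISI ≤ 100 ms,
* void acceptance v ≥ 0.7,
* fixed 100 ms cutoff when a clear intra-burst peak exists but no valley
  passes the void criterion.

A burst is a maximal run of consecutive spikes whose ISIs are all at or
below the channel threshold, kept only when it contains at least
``min_spikes`` spikes (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .core import Burst, ChannelMetrics, SpikeTrainSet

__all__ = [
    "LogISIParams",
    "logisi_threshold",
    "detect_bursts",
    "channel_metrics",
    "analyze_channel",
    "analyze_well",
]


@dataclass(frozen=True)
class LogISIParams:
    """Constants of the log-ISI threshold search."""

    bins_per_decade: int = 10
    isi_cap: float = 0.1  # s; intra-burst peak must sit at or below this ISI
    void_threshold: float = 0.7
    fallback_isi: float = 0.1  # s; used when no valley passes the void test
    smooth_bins: int = 3  # moving-average window on the histogram
    # intra-burst peak must reach this fraction of the tallest histogram
    # peak; rejects stray single-count bins in sparse non-bursting trains
    min_peak_fraction: float = 0.1


def logisi_threshold(
    train: Sequence[float], params: LogISIParams = LogISIParams()
) -> Optional[float]:
    """Burst-defining ISI threshold from the log-ISI histogram, or ``None``.

    Returns ``None`` when the train has fewer than 3 spikes or its histogram
    shows no intra-burst peak (no local maximum at ISI ≤ ``isi_cap``) —
    e.g. a homogeneous Poisson train, whose log-ISI histogram is unimodal at
    the mean ISI.  When an intra-burst peak exists, the threshold is the ISI
    at the first minimum between it and a subsequent peak whose void
    parameter reaches ``void_threshold``; if no valley qualifies, the fixed
    ``fallback_isi`` cutoff is returned.
    """
    t = np.asarray(train, dtype=float)
    if t.size < 3:
        return None
    isi = np.diff(t)
    isi = isi[isi > 0]
    if isi.size < 2:
        return None
    log_isi = np.log10(isi)
    bw = 1.0 / params.bins_per_decade
    lo = np.floor(log_isi.min() / bw) * bw - bw
    hi = np.ceil(log_isi.max() / bw) * bw + bw
    n_bins = max(int(round((hi - lo) / bw)), 3)
    counts, edges = np.histogram(log_isi, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if params.smooth_bins > 1:
        kern = np.ones(params.smooth_bins) / params.smooth_bins
        h = np.convolve(counts.astype(float), kern, mode="same")
    else:
        h = counts.astype(float)

    peaks, _ = _signal.find_peaks(np.concatenate(([0.0], h, [0.0])))
    peaks = peaks - 1  # undo padding
    if peaks.size < 1:
        return None
    log_cap = np.log10(params.isi_cap)
    intra = peaks[centers[peaks] <= log_cap]
    intra = intra[h[intra] >= params.min_peak_fraction * h.max()]
    if intra.size == 0:
        return None  # no intra-burst mode: nothing to separate
    p1 = int(intra[np.argmax(h[intra])])
    later = peaks[peaks > p1]
    if later.size == 0:
        return float(params.fallback_isi)
    for p2 in later:
        seg = h[p1 + 1 : p2]
        if seg.size == 0:
            continue
        m = p1 + 1 + int(np.argmin(seg))
        denom = np.sqrt(h[p1] * h[p2])
        if denom == 0:
            continue
        void = 1.0 - h[m] / denom
        if void >= params.void_threshold:
            return float(10.0 ** centers[m])
    return float(params.fallback_isi)


def detect_bursts(
    train: Sequence[float],
    isi_threshold: Optional[float],
    min_spikes: int = 5,
    channel_id: object = 0,
) -> List[Burst]:
    """Maximal runs of consecutive spikes with ISI ≤ threshold.

    Runs shorter than ``min_spikes`` spikes are discarded; a ``None``
    threshold (no separable ISI modes) yields no bursts.  Burst start/end
    are the first/last spike times of the run, with no padding.
    """
    if min_spikes < 1:
        raise ValueError("min_spikes must be >= 1")
    if isi_threshold is None:
        return []
    if isi_threshold <= 0:
        raise ValueError("isi_threshold must be positive (or None)")
    t = np.asarray(train, dtype=float)
    if t.size < min_spikes:
        return []
    short = np.diff(t) <= isi_threshold
    bursts: List[Burst] = []
    i = 0
    n = t.size
    while i < n - 1:
        if short[i]:
            j = i
            while j < n - 1 and short[j]:
                j += 1
            n_spk = j - i + 1
            if n_spk >= min_spikes:
                bursts.append(Burst(channel_id=channel_id, start=float(t[i]),
                                    end=float(t[j]), n_spikes=n_spk))
            i = j
        else:
            i += 1
    return bursts


def spikes_in_bursts(train: Sequence[float], bursts: Sequence[Burst]) -> int:
    """Number of spikes falling inside any burst interval (inclusive)."""
    t = np.asarray(train, dtype=float)
    if t.size == 0 or not bursts:
        return 0
    inside = np.zeros(t.size, dtype=bool)
    for b in bursts:
        inside |= (t >= b.start) & (t <= b.end)
    return int(inside.sum())


def channel_metrics(
    train: Sequence[float],
    bursts: Sequence[Burst],
    duration: float,
    channel_id: object = 0,
    active_mfr: float = 0.1,
    mbr_min: float = 0.4,
) -> ChannelMetrics:
    """Single-channel metrics: MFR (spikes/s), MBR (bursts/min), mean burst
    duration (s), and RS, the percentage of spikes not belonging to a burst.

    A channel is *active* when its MFR exceeds ``active_mfr`` (0.1 spikes/s)
    and enters the bursting analysis when its MBR is at least ``mbr_min``
    (0.4 bursts/min).  RS is 100 when the channel spikes but never bursts,
    and ``None`` (missing) for a silent channel.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(train, dtype=float)
    n = int(t.size)
    mfr = n / duration
    n_bursts = len(bursts)
    mbr = n_bursts / duration * 60.0
    bd_mean = float(np.mean([b.duration for b in bursts])) if bursts else None
    if n == 0:
        rs: Optional[float] = None
    else:
        rs = 100.0 * (1.0 - spikes_in_bursts(t, bursts) / n)
    return ChannelMetrics(
        channel_id=channel_id,
        mfr=float(mfr),
        mbr=float(mbr),
        bd_mean=bd_mean,
        rs=rs,
        n_spikes=n,
        n_bursts=n_bursts,
        active=mfr > active_mfr,
        bursting_included=mbr >= mbr_min,
    )


def analyze_channel(
    train: Sequence[float],
    duration: float,
    channel_id: object = 0,
    min_spikes: int = 5,
    params: LogISIParams = LogISIParams(),
    active_mfr: float = 0.1,
    mbr_min: float = 0.4,
) -> Tuple[List[Burst], ChannelMetrics, Optional[float]]:
    """Full single-channel chain: log-ISI threshold → bursts → metrics."""
    thr = logisi_threshold(train, params)
    bursts = detect_bursts(train, thr, min_spikes=min_spikes, channel_id=channel_id)
    metrics = channel_metrics(train, bursts, duration, channel_id=channel_id,
                              active_mfr=active_mfr, mbr_min=mbr_min)
    return bursts, metrics, thr


def analyze_well(
    trains: SpikeTrainSet,
    min_spikes: int = 5,
    params: LogISIParams = LogISIParams(),
    active_mfr: float = 0.1,
    mbr_min: float = 0.4,
) -> Tuple[Dict[object, List[Burst]], Dict[object, ChannelMetrics]]:
    """Burst detection and metrics for every channel of a well."""
    bursts: Dict[object, List[Burst]] = {}
    metrics: Dict[object, ChannelMetrics] = {}
    for ch, t in trains.trains.items():
        b, m, _ = analyze_channel(t, trains.duration, channel_id=ch,
                                  min_spikes=min_spikes, params=params,
                                  active_mfr=active_mfr, mbr_min=mbr_min)
        bursts[ch] = b
        metrics[ch] = m
    return bursts, metrics
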