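"""Band-pass filtering and hard-threshold spike detection.

The detection chain mirrors standard MEA practice for cultured networks:
a 200–3000 Hz band-pass followed by a hard threshold at k times the
baseline-noise standard deviation (k = 5 by default).  The noise SD is
estimated robustly with the scaled median absolute deviation so that the
spikes themselves do not inflate the threshold.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import signal

from .core import RawRecording, SpikeTrainSet

__all__ = ["bandpass", "estimate_noise_sd", "detect_spikes"]

logger = logging.getLogger(__name__)

#: MAD → SD scale factor for Gaussian noise
_MAD_SCALE = 1.4826


def bandpass(rec: RawRecording, hp: float = 200.0, lp: float = 3000.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass filter (default 200–3000 Hz).

    Applied forward-backward (``sosfiltfilt``) so spike timestamps are not
    shifted by filter delay; removes DC along with everything below ``hp``.
    """
    if not 0 < hp < lp:
        raise ValueError("need 0 < hp < lp")
    if lp >= rec.fs / 2:
        raise ValueError("low-pass cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, [hp, lp], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return RawRecording(samples=filtered, fs=rec.fs, channel_ids=rec.channel_ids,
                        well_id=rec.well_id, t0=rec.t0)


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust per-channel noise SD: scaled median absolute deviation."""
    med = np.median(trace)
    return _MAD_SCALE * float(np.median(np.abs(trace - med)))


def detect_spikes(rec: RawRecording, k: float = 5.0, dead_time: float = 0.001,
                  bipolar: bool = False,
                  noise_sd: Optional[np.ndarray] = None) -> SpikeTrainSet:
    """Hard-threshold spike detection on a band-pass-filtered recording.

    A spike is registered at each negative-going crossing of −k·σ̂, where σ̂
    is the robust noise SD of the channel; the timestamp is the sample of
    the most negative value within the ``dead_time`` window after the
    crossing, and further crossings within ``dead_time`` of a prior spike
    are suppressed.  With ``bipolar=True`` crossings of either polarity are
    detected (timestamp at the largest absolute excursion).

    Channels with zero variance yield no spikes (a warning is logged).
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    n_dead = max(int(round(dead_time * rec.fs)), 1)
    trains = {}
    for i, ch in enumerate(rec.channel_ids):
        x = rec.samples[i]
        sd = float(noise_sd[i]) if noise_sd is not None else estimate_noise_sd(x)
        if sd == 0.0:
            logger.warning("channel %s is flat (zero variance); no spikes", ch)
            trains[ch] = np.empty(0)
            continue
        thr = k * sd
        if bipolar:
            below = np.abs(x) > thr
        else:
            below = x < -thr
        # indices where the trace enters the supra-threshold region
        crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
        peaks = []
        last = -np.inf
        for c in crossings:
            if c - last < n_dead:
                continue
            w = x[c : c + n_dead]
            off = int(np.argmax(np.abs(w))) if bipolar else int(np.argmin(w))
            peaks.append(c + off)
            last = c + off
        t = (np.asarray(peaks, dtype=float)) / rec.fs + rec.t0
        trains[ch] = t
    return SpikeTrainSet(trains=trains, duration=rec.duration,
                         well_id=rec.well_id, t0=rec.t0)
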