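"""Single-cell patch-clamp feature extraction.

Current clamp: action potentials are detected from the membrane-voltage
rate of rise (dV/dt ≥ 20 mV/ms by default, peak above 0 mV), giving per-AP
threshold and peak; from the step family we extract the rheobase (minimum
injected current evoking ≥ 1 AP), AP amplitude (peak − threshold) and width
(full width at half amplitude), and the mean and instantaneous firing
frequencies at the 100 pA step.

Voltage clamp: per depolarizing step the peak inward current (most negative
sample after blanking the capacitive transient) and the steady-state
outward current (mean over the last 10% of the step) are divided by the
cell capacitance to give current densities J = I/C in pA/pF, reported at
the conventional −30 mV (inward, Na⁺-like) and +80 mV (outward) steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import APFeatures, IVResult, PatchSweepFamily

__all__ = [
    "APEvent",
    "detect_aps",
    "rheobase",
    "firing_frequencies",
    "ap_shape",
    "extract_ap_features",
    "iv_analysis",
    "spontaneous_rate",
]

#: access-resistance inclusion cutoff, MΩ
MAX_ACCESS_RESISTANCE = 15.0


@dataclass(frozen=True)
class APEvent:
    """One detected action potential."""

    peak_time: float  # s
    peak_mv: float
    threshold_time: float  # s
    threshold_mv: float

    @property
    def amplitude(self) -> float:
        return self.peak_mv - self.threshold_mv


def detect_aps(
    sweep: np.ndarray,
    fs: float,
    dvdt_threshold: float = 20.0,
    peak_floor: float = 0.0,
    min_interval: float = 0.002,
) -> List[APEvent]:
    """Detect APs on a current-clamp voltage trace (mV).

    An AP is an upward excursion whose rate of rise reaches
    ``dvdt_threshold`` (mV/ms) and whose peak exceeds ``peak_floor`` (mV).
    The per-AP threshold is the voltage at the first sample before the peak
    where dV/dt first reaches the criterion.  Peaks closer than
    ``min_interval`` to the previous accepted AP are discarded.
    """
    v = np.asarray(sweep, dtype=float)
    if v.size < 3:
        return []
    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    fast = dvdt >= dvdt_threshold
    if not fast.any():
        return []
    # rising-phase onsets: first sample of each run of fast depolarization
    onsets = np.flatnonzero(fast & ~np.concatenate(([False], fast[:-1])))
    events: List[APEvent] = []
    last_peak = -np.inf
    for j, on in enumerate(onsets):
        seg_end = onsets[j + 1] if j + 1 < onsets.size else v.size
        # peak: local max after onset, before the next AP's onset
        win = v[on:seg_end]
        k = on + int(np.argmax(win))
        if v[k] < peak_floor:
            continue
        t_peak = k / fs
        if t_peak - last_peak < min_interval:
            continue
        events.append(
            APEvent(peak_time=t_peak, peak_mv=float(v[k]),
                    threshold_time=on / fs, threshold_mv=float(v[on]))
        )
        last_peak = t_peak
    return events


def _family_aps(family: PatchSweepFamily, dvdt_threshold: float,
                peak_floor: float) -> List[List[APEvent]]:
    if family.mode != "cc":
        raise ValueError("AP analysis requires a current-clamp family")
    return [
        detect_aps(family.sweeps[i], family.fs, dvdt_threshold, peak_floor)
        for i in range(family.n_sweeps)
    ]


def rheobase(family: PatchSweepFamily, dvdt_threshold: float = 20.0,
             peak_floor: float = 0.0) -> Optional[float]:
    """Minimum injected current (pA) evoking at least one AP; ``None`` when
    no sweep fires."""
    aps = _family_aps(family, dvdt_threshold, peak_floor)
    order = np.argsort(family.step_values)
    for i in order:
        if aps[i]:
            return float(family.step_values[i])
    return None


def firing_frequencies(
    family: PatchSweepFamily,
    at_current: float = 100.0,
    dvdt_threshold: float = 20.0,
    peak_floor: float = 0.0,
    mean_ff_n_minus_1: bool = False,
) -> Tuple[Optional[float], Optional[float]]:
    """Mean and instantaneous firing frequency (Hz) at ``at_current`` pA.

    With AP peak times t1..tN on that sweep, the mean firing frequency is
    the ratio of the AP count to the interval between the first and last
    AP — N/(tN − t1) by default, (N−1)/(tN − t1) with
    ``mean_ff_n_minus_1=True`` — and the instantaneous firing frequency is
    1/(t2 − t1).  Both are ``None`` when the sweep has fewer than two APs.
    """
    idx = np.flatnonzero(np.isclose(family.step_values, at_current))
    if idx.size == 0:
        raise KeyError(f"no sweep at {at_current} pA")
    events = detect_aps(family.sweeps[idx[0]], family.fs, dvdt_threshold, peak_floor)
    if len(events) < 2:
        return None, None
    t = np.array([e.peak_time for e in events])
    span = t[-1] - t[0]
    num = (t.size - 1) if mean_ff_n_minus_1 else t.size
    return float(num / span), float(1.0 / (t[1] - t[0]))


def ap_shape(
    family: PatchSweepFamily,
    sweep_current: Optional[float] = None,
    dvdt_threshold: float = 20.0,
    peak_floor: float = 0.0,
) -> Tuple[Optional[float], Optional[float]]:
    """AP amplitude (mV) and width (ms) summarized over the APs of one sweep.

    Amplitude is peak − threshold per AP; width is the full width at half
    amplitude, measured between the crossings of threshold + amplitude/2 on
    either side of the peak.  ``sweep_current`` defaults to the rheobase
    sweep.  Returns ``(None, None)`` when no AP is found.
    """
    if sweep_current is None:
        sweep_current = rheobase(family, dvdt_threshold, peak_floor)
        if sweep_current is None:
            return None, None
    idx = np.flatnonzero(np.isclose(family.step_values, sweep_current))
    if idx.size == 0:
        raise KeyError(f"no sweep at {sweep_current}")
    v = family.sweeps[idx[0]]
    events = detect_aps(v, family.fs, dvdt_threshold, peak_floor)
    if not events:
        return None, None
    amps, widths = [], []
    for e in events:
        amps.append(e.amplitude)
        half = e.threshold_mv + 0.5 * e.amplitude
        k = int(round(e.peak_time * family.fs))
        i = k
        while i > 0 and v[i] > half:
            i -= 1
        j = k
        while j < v.size - 1 and v[j] > half:
            j += 1
        # linear interpolation at the half-amplitude crossings
        t_left = i + (half - v[i]) / (v[i + 1] - v[i]) if v[i + 1] != v[i] else i
        t_right = j - 1 + (half - v[j - 1]) / (v[j] - v[j - 1]) if v[j] != v[j - 1] else j
        widths.append((t_right - t_left) / family.fs * 1000.0)
    return float(np.mean(amps)), float(np.mean(widths))


def extract_ap_features(
    family: PatchSweepFamily,
    at_current: float = 100.0,
    dvdt_threshold: float = 20.0,
    peak_floor: float = 0.0,
) -> APFeatures:
    """All current-clamp features of one cell in a single pass."""
    aps = _family_aps(family, dvdt_threshold, peak_floor)
    ap_times = {
        float(family.step_values[i]): np.array([e.peak_time for e in aps[i]])
        for i in range(family.n_sweeps)
    }
    rb = rheobase(family, dvdt_threshold, peak_floor)
    try:
        mean_ff, inst_ff = firing_frequencies(
            family, at_current, dvdt_threshold, peak_floor
        )
    except KeyError:
        mean_ff, inst_ff = None, None
    amp, width = (None, None) if rb is None else ap_shape(
        family, rb, dvdt_threshold, peak_floor
    )
    excluded = (
        family.access_resistance is not None
        and family.access_resistance > MAX_ACCESS_RESISTANCE
    )
    return APFeatures(
        ap_times=ap_times,
        ap_counts={k: v.size for k, v in ap_times.items()},
        rheobase=rb,
        ap_amplitude=amp,
        ap_width=width,
        mean_ff=mean_ff,
        inst_ff=inst_ff,
        at_current=at_current,
        excluded=excluded,
    )


def iv_analysis(
    family: PatchSweepFamily,
    capacitance: Optional[float] = None,
    blank_ms: float = 1.0,
    inward_window_ms: float = 50.0,
    steady_fraction: float = 0.1,
) -> IVResult:
    """Per-step peak inward and steady-state outward currents and densities.

    The peak inward current is the most negative sample between
    ``blank_ms`` (capacitive-transient blanking) and ``inward_window_ms``
    after step onset, clipped at 0 so depolarizations with no inward
    component report 0.  The steady-state outward current is the mean over
    the last ``steady_fraction`` of the step, clipped at 0 from below.
    Densities are J = I / C exactly.
    """
    if family.mode != "vc":
        raise ValueError("iv_analysis requires a voltage-clamp family")
    c = capacitance if capacitance is not None else family.capacitance
    if c is None or c <= 0:
        raise ValueError("capacitance must be positive")
    fs = family.fs
    on = int(round(family.step_window[0] * fs))
    off = int(round(family.step_window[1] * fs))
    b0 = on + int(round(blank_ms * 1e-3 * fs))
    b1 = min(on + int(round(inward_window_ms * 1e-3 * fs)), off)
    ss0 = off - max(int(round(steady_fraction * (off - on))), 1)
    peak_in = np.empty(family.n_sweeps)
    steady_out = np.empty(family.n_sweeps)
    for i in range(family.n_sweeps):
        tr = family.sweeps[i]
        peak_in[i] = min(float(tr[b0:b1].min()), 0.0)
        steady_out[i] = max(float(tr[ss0:off].mean()), 0.0)
    return IVResult(
        step_mv=family.step_values.copy(),
        peak_inward_pa=peak_in,
        steady_outward_pa=steady_out,
        j_inward=peak_in / c,
        j_outward=steady_out / c,
        capacitance=float(c),
    )


def spontaneous_rate(
    trace: np.ndarray,
    fs: float,
    duration: Optional[float] = None,
    dvdt_threshold: float = 20.0,
    peak_floor: float = 0.0,
) -> float:
    """Spontaneous firing rate (Hz) from a continuous recording at the
    −40 mV threshold potential: detected AP count / duration."""
    trace = np.asarray(trace, dtype=float)
    if duration is None:
        duration = trace.size / fs
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(detect_aps(trace, fs, dvdt_threshold, peak_floor)) / duration
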