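"""Core data containers shared across the analysis modules.

All times are in seconds (floats), sample indices are 0-based, voltages
in mV (patch) or µV (extracellular), currents in pA, capacitance in pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "RawRecording",
    "SpikeTrainSet",
    "Burst",
    "ChannelMetrics",
    "NetworkBurst",
    "RateProfile",
    "PatchSweepFamily",
    "APFeatures",
    "IVResult",
]


@dataclass
class RawRecording:
    """Multichannel extracellular voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in µV.
    fs : float
        Sampling rate in Hz.
    channel_ids : sequence
        One identifier per row of ``samples``.
    well_id : str
        Well the channels belong to.
    t0 : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    channel_ids: Sequence
    well_id: str = "well"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("one channel id per sample row required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times for one well/recording."""

    trains: Dict[object, np.ndarray]
    duration: float
    well_id: str = "well"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean: Dict[object, np.ndarray] = {}
        for ch, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times on channel {ch} not strictly increasing")
            clean[ch] = t
        self.trains = clean

    @property
    def channel_ids(self) -> List:
        return list(self.trains.keys())

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def pooled(self) -> np.ndarray:
        """All spike times of the well, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


@dataclass(frozen=True)
class Burst:
    """A single-channel burst: a run of spikes with short ISIs."""

    channel_id: object
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ChannelMetrics:
    """Single-channel activity metrics.

    ``rs`` (percentage of random spikes, i.e. spikes outside bursts) is
    ``None`` for a channel with zero spikes so that well averages are not
    biased by silent electrodes.
    """

    channel_id: object
    mfr: float  # spikes/s
    mbr: float  # bursts/min
    bd_mean: Optional[float]  # s, None when no bursts
    rs: Optional[float]  # %, None when no spikes
    n_spikes: int
    n_bursts: int
    active: bool
    bursting_included: bool


@dataclass
class NetworkBurst:
    """Network-level event: near-simultaneous bursts on many channels."""

    start: float
    end: float
    participating_channels: Set
    peak_time: Optional[float] = None
    peak_rate: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_channels(self) -> int:
        return len(self.participating_channels)


@dataclass
class RateProfile:
    """Population firing-rate profile: pooled spike counts per uniform bin,
    expressed in spikes/s."""

    bin_edges: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.bin_edges.size != self.rate.size + 1:
            raise ValueError("need len(bin_edges) == len(rate) + 1")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PatchSweepFamily:
    """Family of patch-clamp sweeps sharing a step protocol.

    ``mode`` is ``"cc"`` (current clamp: sweeps in mV, steps in pA) or
    ``"vc"`` (voltage clamp: sweeps in pA, steps in mV).  The step is applied
    during ``step_window = (start_s, end_s)``; outside it the cell sits at
    the holding level.
    """

    mode: str
    sweeps: np.ndarray  # (n_sweeps, n_samples)
    fs: float
    step_values: np.ndarray  # pA (cc) or mV (vc), one per sweep
    step_window: Tuple[float, float]
    capacitance: Optional[float] = None  # pF
    holding: Optional[float] = None  # mV
    access_resistance: Optional[float] = None  # MΩ
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.mode not in ("cc", "vc"):
            raise ValueError("mode must be 'cc' or 'vc'")
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.step_values = np.asarray(self.step_values, dtype=float)
        if self.step_values.size != self.sweeps.shape[0]:
            raise ValueError("one step value per sweep required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.capacitance is not None and self.capacitance <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.fs


@dataclass
class APFeatures:
    """Single-cell action-potential features from a current-clamp family."""

    ap_times: Dict[float, np.ndarray]  # step (pA) -> AP peak times (s)
    ap_counts: Dict[float, int]
    rheobase: Optional[float]  # pA
    ap_amplitude: Optional[float]  # mV, peak − threshold
    ap_width: Optional[float]  # ms, full width at half amplitude
    mean_ff: Optional[float]  # Hz at the reference current
    inst_ff: Optional[float]  # Hz at the reference current
    at_current: float = 100.0
    excluded: bool = False  # access-resistance cutoff


@dataclass
class IVResult:
    """Per-step current amplitudes and current densities from a VC family."""

    step_mv: np.ndarray
    peak_inward_pa: np.ndarray  # ≤ 0
    steady_outward_pa: np.ndarray
    j_inward: np.ndarray  # pA/pF
    j_outward: np.ndarray  # pA/pF
    capacitance: float

    def density_at(self, step_mv: float, which: str = "inward") -> float:
        idx = np.flatnonzero(np.isclose(self.step_mv, step_mv))
        if idx.size == 0:
            raise KeyError(f"no step at {step_mv} mV")
        arr = self.j_inward if which == "inward" else self.j_outward
        return float(arr[idx[0]])
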