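"""Plain-text / HDF5 persistence for the pipeline's data products.

Spike trains, bursts and metrics travel as CSV; raw traces and patch sweep
families as HDF5; ground truth as JSON.  These formats define the
ingestion contract for externally acquired data as well: any acquisition
system able to export a ``well_id, channel_id, spike_time_s`` spike table
can enter the pipeline at the burst stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .core import Burst, ChannelMetrics, NetworkBurst, PatchSweepFamily, RawRecording, SpikeTrainSet
from .synth import GroundTruth

PathLike = Union[str, Path]


# ----------------------------------------------------------------- CSV ----

def write_spike_trains(trains: SpikeTrainSet, path: PathLike) -> None:
    rows = [
        {"well_id": trains.well_id, "channel_id": ch, "spike_time_s": t}
        for ch, times in trains.trains.items()
        for t in times
    ]
    df = pd.DataFrame(rows, columns=["well_id", "channel_id", "spike_time_s"])
    with open(path, "w") as fh:
        fh.write(f"# duration_s={trains.duration} t0_s={trains.t0} "
                 f"channels={','.join(str(c) for c in trains.channel_ids)}\n")
        df.to_csv(fh, index=False)


def read_spike_trains(path: PathLike, duration: Optional[float] = None) -> SpikeTrainSet:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if duration is None:
        duration = float(meta.get("duration_s", 0)) or float(df["spike_time_s"].max())
    trains: Dict[object, np.ndarray] = {}
    if "channels" in meta:
        for c in meta["channels"].split(","):
            try:
                trains[int(c)] = np.empty(0)
            except ValueError:
                trains[c] = np.empty(0)
    for ch, g in df.groupby("channel_id"):
        trains[ch] = np.sort(g["spike_time_s"].to_numpy(dtype=float))
    well = str(df["well_id"].iloc[0]) if len(df) else "well"
    return SpikeTrainSet(trains=trains, duration=duration, well_id=well,
                         t0=float(meta.get("t0_s", 0.0)))


def write_bursts(bursts: Dict[object, Sequence[Burst]], path: PathLike,
                 well_id: str = "well") -> None:
    rows = [
        {"well_id": well_id, "channel_id": b.channel_id, "start_s": b.start,
         "end_s": b.end, "n_spikes": b.n_spikes}
        for blist in bursts.values() for b in blist
    ]
    pd.DataFrame(rows, columns=["well_id", "channel_id", "start_s", "end_s",
                                "n_spikes"]).to_csv(path, index=False)


def read_bursts(path: PathLike) -> Dict[object, List[Burst]]:
    df = pd.read_csv(path)
    out: Dict[object, List[Burst]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["channel_id"], []).append(
            Burst(channel_id=r["channel_id"], start=float(r["start_s"]),
                  end=float(r["end_s"]), n_spikes=int(r["n_spikes"]))
        )
    return out


def write_channel_metrics(metrics: Dict[object, ChannelMetrics], path: PathLike,
                          well_id: str = "well") -> None:
    rows = [dict(vars(m), well_id=well_id) for m in metrics.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_network_bursts(nbs: Sequence[NetworkBurst], path: PathLike,
                         well_id: str = "well") -> None:
    rows = [
        {"well_id": well_id, "start_s": nb.start, "end_s": nb.end,
         "n_channels": nb.n_channels, "peak_time_s": nb.peak_time,
         "peak_rate_hz": nb.peak_rate,
         "channels": ";".join(str(c) for c in sorted(nb.participating_channels, key=str))}
        for nb in nbs
    ]
    pd.DataFrame(rows, columns=["well_id", "start_s", "end_s", "n_channels",
                                "peak_time_s", "peak_rate_hz", "channels"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------- HDF5 ----

def write_raw_recording(rec: RawRecording, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(rec.well_id, data=rec.samples)
        d.attrs["fs_hz"] = rec.fs
        d.attrs["t0_s"] = rec.t0
        d.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]


def read_raw_recording(path: PathLike, well_id: Optional[str] = None) -> RawRecording:
    with h5py.File(path, "r") as f:
        if well_id is None:
            well_id = next(iter(f.keys()))
        d = f[well_id]
        ids = [c.decode() if isinstance(c, bytes) else str(c)
               for c in d.attrs["channel_ids"]]
        ids = [int(c) if c.isdigit() else c for c in ids]
        return RawRecording(samples=d[...], fs=float(d.attrs["fs_hz"]),
                            channel_ids=ids, well_id=well_id,
                            t0=float(d.attrs["t0_s"]))


def write_sweep_family(fam: PatchSweepFamily, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sweeps", data=fam.sweeps)
        d.attrs["mode"] = fam.mode
        d.attrs["fs_hz"] = fam.fs
        d.attrs["step_values"] = fam.step_values
        d.attrs["step_window_s"] = fam.step_window
        d.attrs["cell_id"] = fam.cell_id
        for name, val in (("capacitance_pf", fam.capacitance),
                          ("holding_mv", fam.holding),
                          ("access_resistance_mohm", fam.access_resistance)):
            if val is not None:
                d.attrs[name] = val


def read_sweep_family(path: PathLike) -> PatchSweepFamily:
    with h5py.File(path, "r") as f:
        d = f["sweeps"]
        a = d.attrs
        return PatchSweepFamily(
            mode=str(a["mode"]), sweeps=d[...], fs=float(a["fs_hz"]),
            step_values=np.asarray(a["step_values"]),
            step_window=tuple(float(x) for x in a["step_window_s"]),
            capacitance=float(a["capacitance_pf"]) if "capacitance_pf" in a else None,
            holding=float(a["holding_mv"]) if "holding_mv" in a else None,
            access_resistance=(float(a["access_resistance_mohm"])
                               if "access_resistance_mohm" in a else None),
            cell_id=str(a["cell_id"]),
        )


# ---------------------------------------------------------------- JSON ----

class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, frozenset):
            return sorted(o, key=str)
        return super().default(o)


def write_ground_truth(gt: GroundTruth, path: PathLike) -> None:
    payload = {k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
               for k, v in dataclasses.asdict(gt).items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, cls=_NumpyEncoder, indent=1)
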