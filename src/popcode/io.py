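"""Plain-text and HDF5 serialization of the pipeline's artifacts.

Formats:

* spike tables: TSV with columns ``unit_id, spike_time_s`` and a
  ``# duration_s=...`` header comment;
* epochs: BED-like TSV ``start_s, end_s, label``;
* velocity: TSV ``time_s, velocity_cm_s``;
* pattern distributions: TSV ``pattern_index, probability``;
* maximum-entropy models: YAML (N, order, h, J, logZ);
* rasters: HDF5 (uint8 matrix, bin width, unit ids).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import BinaryRaster, EpochSet, PatternDistribution, SortedUnit, SpikeTrainSet, VelocityTrace
from .maxent import MaxEntModel

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_epochs",
    "read_epochs",
    "write_velocity",
    "read_velocity",
    "write_pattern_distribution",
    "read_pattern_distribution",
    "write_model",
    "read_model",
    "write_raster",
    "read_raster",
]


def write_spikes(path: str | Path, s: SpikeTrainSet) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_s={s.duration}\tgroup={s.group_label}\n")
        fh.write("unit_id\tspike_time_s\n")
        for u in s.units:
            for t in u.spike_times:
                fh.write(f"{u.unit_id}\t{t:.6f}\n")


def read_spikes(path: str | Path, group_label: str | None = None) -> SpikeTrainSet:
    path = Path(path)
    duration = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for field in first[1:].split():
            if field.startswith("duration_s="):
                duration = float(field.split("=", 1)[1])
            if field.startswith("group=") and group_label is None:
                group_label = field.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    units = [
        SortedUnit(unit_id=int(uid), spike_times=grp["spike_time_s"].to_numpy())
        for uid, grp in df.groupby("unit_id")
    ]
    if duration is None:
        duration = float(df["spike_time_s"].max()) + 1.0
    return SpikeTrainSet(units=units, duration=duration, group_label=group_label or "unknown")


def write_epochs(path: str | Path, e: EpochSet) -> None:
    pd.DataFrame({"start_s": e.starts, "end_s": e.ends, "label": e.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_epochs(path: str | Path) -> EpochSet:
    df = pd.read_csv(path, sep="\t")
    return EpochSet(
        starts=df["start_s"].to_numpy(),
        ends=df["end_s"].to_numpy(),
        labels=df["label"].to_numpy(dtype=object),
    )


def write_velocity(path: str | Path, v: VelocityTrace) -> None:
    pd.DataFrame({"time_s": v.time, "velocity_cm_s": v.velocity}).to_csv(
        path, sep="\t", index=False
    )


def read_velocity(path: str | Path, step: float = 0.010) -> VelocityTrace:
    df = pd.read_csv(path, sep="\t")
    return VelocityTrace(
        time=df["time_s"].to_numpy(), velocity=df["velocity_cm_s"].to_numpy(), step=step
    )


def write_pattern_distribution(path: str | Path, d: PatternDistribution) -> None:
    pd.DataFrame({"pattern_index": np.arange(len(d.p)), "probability": d.p}).to_csv(
        path, sep="\t", index=False
    )


def read_pattern_distribution(path: str | Path, n_samples: int | None = None) -> PatternDistribution:
    df = pd.read_csv(path, sep="\t")
    p = df["probability"].to_numpy()
    n = int(np.log2(len(p)))
    return PatternDistribution(N=n, p=p, n_samples=n_samples)


def write_model(path: str | Path, m: MaxEntModel, metadata: dict | None = None) -> None:
    doc = {
        "N": int(m.N),
        "order": int(m.order),
        "h": [float(x) for x in m.h],
        "J": [[float(x) for x in row] for row in m.J],
        "logZ": float(m.logZ),
    }
    if metadata:
        doc["metadata"] = metadata
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path: str | Path) -> MaxEntModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MaxEntModel(
        N=doc["N"],
        order=doc["order"],
        h=np.array(doc["h"]),
        J=np.array(doc["J"]),
        logZ=doc["logZ"],
    )


def write_raster(path: str | Path, r: BinaryRaster) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=r.matrix, compression="gzip")
        fh.attrs["bin_width"] = r.bin_width
        fh.attrs["t0"] = r.t0
        fh.create_dataset("unit_ids", data=np.asarray(r.unit_ids))


def read_raster(path: str | Path) -> BinaryRaster:
    with h5py.File(path, "r") as fh:
        return BinaryRaster(
            matrix=fh["matrix"][()],
            bin_width=float(fh.attrs["bin_width"]),
            t0=float(fh.attrs["t0"]),
            unit_ids=fh["unit_ids"][()],
        )
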