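"""Core containers and text-based readers/writers.

All on-disk formats are plain text: tab-separated tables for time series and
voltage-clamp sweeps, multi-page TIFF plus a YAML sidecar for volumes, and CSV
for metric tables.  Physical units are fixed by convention: time in seconds,
membrane potential in mV, current in pA, lengths in µm, capacitance in pF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError

__all__ = [
    "TimeSeriesRecording",
    "VolumeImage",
    "Sweep",
    "SweepSet",
    "read_timeseries",
    "write_timeseries",
    "read_volume",
    "write_volume",
    "read_sweeps",
    "write_sweeps",
    "write_metrics",
]


@dataclass
class TimeSeriesRecording:
    """Uniformly sampled multi-channel recording.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with a constant step
        (relative tolerance 1e-6).
    channels : dict of str -> ndarray
        Named signal arrays, all of the same length as ``time``. Conventional
        names: ``fura_ratio`` (dimensionless), ``sarcomere_length`` (µm),
        ``stimulus`` (V), ``membrane_potential`` (mV), ``temperature`` (°C).
    sampling_rate : float
        Samples per second.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise FormatError("time axis must be 1-D with at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise FormatError("time axis must be strictly increasing")
        step = steps.mean()
        if np.max(np.abs(steps - step)) > 1e-6 * max(abs(step), 1e-30):
            raise FormatError("time axis must be uniformly sampled")
        for name, sig in self.channels.items():
            arr = np.asarray(sig, dtype=float)
            if arr.shape != self.time.shape:
                raise FormatError(
                    f"channel {name!r} has length {arr.size}, expected {self.time.size}"
                )
            self.channels[name] = arr

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(
                f"recording has no channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class VolumeImage:
    """3-D intensity volume with physical voxel size.

    ``voxels`` is indexed (z, y, x); ``voxel_size_um`` gives the spacing per
    axis in the same order, in µm.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel: str = "unknown"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError("volume must be 3-D (z, y, x)")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite intensities")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise FormatError("voxel_size_um must be three positive values (z, y, x)")
        self.voxel_size_um = vs

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass
class Sweep:
    """One voltage- or current-clamp sweep: time (s) and signal (pA or mV)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise FormatError("sweep time and signal must be 1-D and equally long")


@dataclass
class SweepSet:
    """Family of sweeps with the commanded protocol attached.

    ``protocol`` has one row per sweep.  Required columns depend on the
    protocol kind; ``v_test_mv``, ``pulse_start_s`` and ``pulse_end_s`` are
    always present for voltage-clamp data.
    """

    sweeps: list[Sweep]
    protocol: pd.DataFrame
    capacitance_pf: float
    signal_units: str = "pA"
    kind: str = "iv"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sweeps) != len(self.protocol):
            raise FormatError(
                f"{len(self.sweeps)} sweeps but {len(self.protocol)} protocol rows"
            )
        if self.capacitance_pf <= 0:
            raise FormatError("capacitance must be positive (pF)")


# ---------------------------------------------------------------------------
# time series


def write_timeseries(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording as a tab-separated table with a header row."""
    path = Path(path)
    names = list(rec.channels)
    data = np.column_stack([rec.time] + [rec.channels[n] for n in names])
    header = "\t".join(["time_s"] + names)
    np.savetxt(path, data, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_timeseries(path: str | Path) -> TimeSeriesRecording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split("\t")
    if not cols or cols[0] != "time_s":
        raise FormatError(
            f"{path}: expected a tab-separated header starting with 'time_s', got {header!r}"
        )
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != len(cols):
        raise FormatError(f"{path}: {data.shape[1]} columns but {len(cols)} header names")
    time = data[:, 0]
    channels = {name: data[:, i] for i, name in enumerate(cols) if i > 0}
    rate = 1.0 / float(np.mean(np.diff(time)))
    return TimeSeriesRecording(time=time, channels=channels, sampling_rate=rate)


# ---------------------------------------------------------------------------
# volumes


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as multi-page TIFF with a YAML voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.voxels.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"voxel_size_zyx_um": list(vol.voxel_size_um), "channel": vol.channel}, fh
        )


def read_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise FormatError(
            f"{sidecar} not found: voxel size metadata is required and never defaulted"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "voxel_size_zyx_um" not in meta:
        raise FormatError(f"{sidecar}: missing key 'voxel_size_zyx_um'")
    voxels = tifffile.imread(path)
    return VolumeImage(
        voxels=voxels,
        voxel_size_um=tuple(meta["voxel_size_zyx_um"]),
        channel=str(meta.get("channel", "unknown")),
    )


# ---------------------------------------------------------------------------
# sweeps


def write_sweeps(ss: SweepSet, directory: str | Path) -> None:
    """Write one TSV per sweep plus a protocol YAML into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sw in enumerate(ss.sweeps):
        np.savetxt(
            directory / f"sweep_{i:03d}.tsv",
            np.column_stack([sw.time, sw.signal]),
            delimiter="\t",
            header=f"time_s\tsignal_{ss.signal_units}",
            comments="",
            fmt="%.10g",
        )
    proto = {
        "kind": ss.kind,
        "capacitance_pf": float(ss.capacitance_pf),
        "signal_units": ss.signal_units,
        "meta": {k: v for k, v in ss.meta.items()},
        "sweeps": ss.protocol.to_dict(orient="records"),
    }
    with open(directory / "protocol.yaml", "w") as fh:
        yaml.safe_dump(proto, fh)


def read_sweeps(directory: str | Path) -> SweepSet:
    directory = Path(directory)
    proto_path = directory / "protocol.yaml"
    if not proto_path.exists():
        raise FormatError(f"{proto_path} not found: sweep sets require a protocol file")
    with open(proto_path) as fh:
        proto = yaml.safe_load(fh)
    rows = proto.get("sweeps")
    if not rows:
        raise FormatError(f"{proto_path}: no per-sweep protocol entries")
    sweeps = []
    for i in range(len(rows)):
        f = directory / f"sweep_{i:03d}.tsv"
        if not f.exists():
            raise FormatError(f"{f} referenced by protocol but missing")
        data = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=2)
        sweeps.append(Sweep(time=data[:, 0], signal=data[:, 1]))
    return SweepSet(
        sweeps=sweeps,
        protocol=pd.DataFrame(rows),
        capacitance_pf=float(proto["capacitance_pf"]),
        signal_units=str(proto.get("signal_units", "pA")),
        kind=str(proto.get("kind", "iv")),
        meta=dict(proto.get("meta") or {}),
    )


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics table as CSV (no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def dataclass_to_dict(obj) -> dict:
    """Plain-dict view of a spec dataclass, for provenance records."""
    return dataclasses.asdict(obj)
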