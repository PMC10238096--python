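"""Session container and file I/O (HDF5 canonical, CSV directory for fixtures).

A :class:`Session` holds everything recorded simultaneously: the
fluorescence trace matrix (objects x frames) with its frame rate,
behavioral traces at the video rate, ROI metadata (center positions in mm,
sizes), the object-to-ROI map with population labels and same-axon pair
ids, optional ground-truth events (for simulated sessions), and a
provenance log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BehaviorTraces

POPULATIONS = ("ACh", "NA", "VCIN", "mCherry", "bleb")

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A required group/column is missing or malformed in a session file."""


@dataclass
class Session:
    session_id: str
    fluor: np.ndarray           # (n_objects, n_frames)
    fs_fluor: float
    behavior: BehaviorTraces
    rois: pd.DataFrame          # roi_id, x_mm, y_mm, size_um
    objects: pd.DataFrame       # object_id, population, roi_id, pair_id
    truth_events: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.fluor.ndim != 2:
            raise SchemaError("fluorescence matrix must be 2-D (objects x frames)")
        if len(self.objects) != self.fluor.shape[0]:
            raise SchemaError("objects table length must match fluorescence rows")
        unknown = set(self.objects["population"]) - set(POPULATIONS)
        if unknown:
            raise SchemaError(f"unknown population labels: {sorted(unknown)}")
        if not set(self.objects["roi_id"]).issubset(set(self.rois["roi_id"])):
            raise SchemaError("every object must map to a known ROI")
        nan_frac = np.isnan(self.fluor).mean(axis=1) if self.fluor.size else np.array([])
        if np.any(nan_frac > 0.10):
            warnings.warn("some fluorescence traces have >10% NaN samples")

    # ------------------------------------------------------------------
    @property
    def n_objects(self) -> int:
        return self.fluor.shape[0]

    @property
    def t_fluor(self) -> np.ndarray:
        return np.arange(self.fluor.shape[1]) / self.fs_fluor

    @property
    def duration_s(self) -> float:
        return self.fluor.shape[1] / self.fs_fluor

    def roi_positions(self) -> np.ndarray:
        """Per-object ROI center coordinates in mm, shape (n_objects, 2)."""
        pos = self.rois.set_index("roi_id")[["x_mm", "y_mm"]]
        return pos.loc[self.objects["roi_id"]].to_numpy(dtype=float)

    def behavior_on(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """Behavioral channels linearly interpolated onto time grid ``t``."""
        b = self.behavior
        out = {}
        for name in ("wheel_speed", "pupil", "mei_whisker", "mei_snout",
                     "mei_jaw", "mei_fullface"):
            out[name] = np.interp(t, b.time_s, getattr(b, name))
        return out

    def log(self, message: str) -> None:
        self.provenance.append(message)


# ----------------------------------------------------------------------
# HDF5
# ----------------------------------------------------------------------

def _write_frame(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object or data.dtype.kind in "US":
            data = np.asarray([str(v) for v in data], dtype="S64")
        group.create_dataset(col, data=data)
    group.attrs["columns"] = json.dumps(list(df.columns))


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    out = {}
    for col in cols:
        data = group[col][()]
        if data.dtype.kind == "S":
            data = np.asarray([v.decode() for v in data])
        out[col] = data
    return pd.DataFrame(out)


def save_hdf5(session: Session, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(session.provenance)
        g = f.create_group("fluorescence")
        g.create_dataset("traces", data=session.fluor)
        g.attrs["fs_hz"] = session.fs_fluor
        _write_frame(f.create_group("behavior"), session.behavior.to_frame())
        meta = f.create_group("meta")
        _write_frame(meta.create_group("rois"), session.rois)
        _write_frame(meta.create_group("objects"), session.objects)
        if session.truth_events is not None:
            _write_frame(f.create_group("truth"), session.truth_events)
    return path


def load_hdf5(path: str | Path) -> Session:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for group in ("fluorescence", "behavior", "meta/rois", "meta/objects"):
            if group not in f:
                raise SchemaError(f"missing required group '{group}' in {path}")
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise SchemaError("unrecognized schema version")
        fluor = f["fluorescence/traces"][()]
        fs = float(f["fluorescence"].attrs["fs_hz"])
        behavior = BehaviorTraces.from_frame(_read_frame(f["behavior"]))
        rois = _read_frame(f["meta/rois"])
        objects = _read_frame(f["meta/objects"])
        truth = _read_frame(f["truth"]) if "truth" in f else None
        prov = json.loads(f.attrs.get("provenance", "[]"))
        sid = str(f.attrs.get("session_id", path.stem))
    rois["roi_id"] = rois["roi_id"].astype(int)
    objects["roi_id"] = objects["roi_id"].astype(int)
    objects["pair_id"] = objects["pair_id"].astype(int)
    return Session(session_id=sid, fluor=fluor, fs_fluor=fs, behavior=behavior,
                   rois=rois, objects=objects, truth_events=truth,
                   provenance=prov + [f"loaded from {path.name}"])


# ----------------------------------------------------------------------
# CSV directory (small fixtures, docs)
# ----------------------------------------------------------------------

def save_csv_dir(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    fl = pd.DataFrame(session.fluor.T, columns=session.objects["object_id"])
    fl.insert(0, "time_s", session.t_fluor)
    fl.to_csv(path / "fluorescence.csv", index=False, float_format=fmt)
    session.behavior.to_frame().to_csv(path / "behavior.csv", index=False,
                                       float_format=fmt)
    session.rois.to_csv(path / "rois.csv", index=False, float_format=fmt)
    session.objects.to_csv(path / "objects.csv", index=False)
    if session.truth_events is not None:
        session.truth_events.to_csv(path / "truth_events.csv", index=False,
                                    float_format=fmt)
    (path / "meta.json").write_text(json.dumps({
        "session_id": session.session_id,
        "fs_fluor_hz": session.fs_fluor,
        "schema_version": SCHEMA_VERSION,
        "provenance": session.provenance,
    }, indent=2))
    return path


def load_csv_dir(path: str | Path) -> Session:
    path = Path(path)
    for name in ("fluorescence.csv", "behavior.csv", "rois.csv",
                 "objects.csv", "meta.json"):
        if not (path / name).exists():
            raise SchemaError(f"missing required file '{name}' in {path}")
    meta = json.loads((path / "meta.json").read_text())
    fl = pd.read_csv(path / "fluorescence.csv")
    fluor = fl.drop(columns=["time_s"]).to_numpy().T
    behavior = BehaviorTraces.from_frame(pd.read_csv(path / "behavior.csv"))
    rois = pd.read_csv(path / "rois.csv")
    objects = pd.read_csv(path / "objects.csv")
    truth = None
    if (path / "truth_events.csv").exists():
        truth = pd.read_csv(path / "truth_events.csv")
    return Session(session_id=meta["session_id"], fluor=fluor,
                   fs_fluor=float(meta["fs_fluor_hz"]), behavior=behavior,
                   rois=rois, objects=objects, truth_events=truth,
                   provenance=list(meta.get("provenance", []))
                   + [f"loaded from {path.name}"])


def load_session(path: str | Path, format: str | None = None) -> Session:
    """Load a session from HDF5 (``.h5``) or a CSV directory."""
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return load_hdf5(path)
    if format == "csv-dir":
        return load_csv_dir(path)
    raise ValueError(f"unknown session format: {format}")


def save_session(session: Session, path: str | Path,
                 format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.suffix == "" else "hdf5"
    if format == "hdf5":
        return save_hdf5(session, path)
    if format == "csv-dir":
        return save_csv_dir(session, path)
    raise ValueError(f"unknown session format: {format}")
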