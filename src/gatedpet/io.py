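"""File round-tripping: CSV streams, gated NIfTI series, YAML configs.

External formats:

- Event stream CSV: columns ``t_s,x_mm,y_mm,z_mm`` (header required).
- Trigger stream CSV: column ``t_s``.
- Gated image series: 4D NIfTI-1 (x, y, z, gate) with the voxel size in
  the affine, plus a sidecar JSON of identical basename carrying
  ``period_s``, ``n_gates``, gating bookkeeping, the software version and
  a config hash when available.
- CurveSpec / PhantomConfig / CohortSpec: YAML with the dataclass field
  names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError
from .gating import GatedImageSeries
from .phantom.cohort import CohortSpec
from .phantom.geometry import PhantomConfig
from .phantom.listmode import EventStream, TriggerStream
from .phantom.synthesis import CurveSpec

__all__ = [
    "write_events", "read_events", "write_triggers", "read_triggers",
    "write_gated_series", "read_gated_series",
    "write_yaml", "read_curve_spec", "read_phantom_config", "read_cohort_spec",
    "config_hash",
]

PathLike = Union[str, Path]

EVENT_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm"]


def config_hash(obj) -> str:
    """Short deterministic hash of a dataclass/dict configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# -- CSV streams ------------------------------------------------------------

def write_events(events: EventStream, path: PathLike) -> None:
    pd.DataFrame({
        "t_s": events.t, "x_mm": events.x, "y_mm": events.y, "z_mm": events.z,
    }).to_csv(path, index=False)


def read_events(path: PathLike) -> EventStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse event CSV {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"event CSV {path} lacks columns {missing}")
    df = df[EVENT_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        raise DataError(
            f"event CSV {path}: unparseable/missing value at data line "
            f"{int(np.argmax(bad.values)) + 2}")
    return EventStream(df["t_s"].to_numpy(), df["x_mm"].to_numpy(),
                       df["y_mm"].to_numpy(), df["z_mm"].to_numpy())


def write_triggers(triggers: TriggerStream, path: PathLike) -> None:
    pd.DataFrame({"t_s": triggers.times}).to_csv(path, index=False)


def read_triggers(path: PathLike) -> TriggerStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse trigger CSV {path}: {exc}") from exc
    if "t_s" not in df.columns:
        raise DataError(f"trigger CSV {path} lacks column 't_s'")
    return TriggerStream(df["t_s"].to_numpy())


# -- gated NIfTI ------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_gated_series(series: GatedImageSeries, path: PathLike,
                       extra_meta: dict | None = None) -> None:
    """4D NIfTI (x, y, z, gate) + sidecar JSON with gating metadata."""
    path = Path(path)
    data = np.moveaxis(series.data, 0, -1).astype(np.float32)
    affine = np.diag([series.voxel_size] * 3 + [1.0])
    affine[:3, 3] = np.asarray(series.origin) + series.voxel_size / 2.0
    nib.save(nib.Nifti1Image(data, affine), str(path))
    meta = {
        "period_s": series.period_estimate,
        "n_gates": series.n_gates,
        "gate_mode": "per-beat linear phase",
        "voxel_size_mm": series.voxel_size,
        "origin_mm": np.asarray(series.origin).tolist(),
        "accepted_beats": series.accepted_beats,
        "rejected_beats": series.rejected_beats,
        "discarded_events": series.discarded_events,
        "software_version": __version__,
    }
    meta.update(series.meta)
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))


def read_gated_series(path: PathLike) -> GatedImageSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 4D gated series")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise DataError(f"missing sidecar JSON {sidecar}")
    meta = json.loads(sidecar.read_text())
    voxel = float(meta.get("voxel_size_mm", abs(img.affine[0, 0])))
    origin = np.asarray(meta.get(
        "origin_mm", img.affine[:3, 3] - voxel / 2.0), dtype=float)
    series = GatedImageSeries(
        data=np.moveaxis(data, -1, 0),
        voxel_size=voxel, origin=origin,
        period_estimate=float(meta["period_s"]),
        n_gates=int(meta["n_gates"]),
        accepted_beats=int(meta.get("accepted_beats", 0)),
        rejected_beats=int(meta.get("rejected_beats", 0)),
        discarded_events=int(meta.get("discarded_events", 0)),
        meta={k: v for k, v in meta.items() if k not in {
            "period_s", "n_gates", "voxel_size_mm", "origin_mm",
            "accepted_beats", "rejected_beats", "discarded_events"}},
    )
    return series


# -- YAML configs ------------------------------------------------------------

def write_yaml(obj, path: PathLike) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = dataclasses.asdict(obj)
    elif isinstance(obj, dict):
        payload = obj
    else:
        raise DataError(f"cannot serialize {type(obj)} to YAML")
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _load_yaml(path: PathLike) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        raise DataError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise DataError(f"YAML {path} must contain a mapping")
    return data


def _from_mapping(cls, data: dict, path):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise DataError(f"{path}: unknown {cls.__name__} fields {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("grid_shape", "origin", "edv", "esv", "hr", "pfr",
                "third_mfr", "tpfr"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise DataError(f"{path}: invalid {cls.__name__}: {exc}") from exc


def read_curve_spec(path: PathLike) -> CurveSpec:
    return _from_mapping(CurveSpec, _load_yaml(path), path)


def read_phantom_config(path: PathLike) -> PhantomConfig:
    return _from_mapping(PhantomConfig, _load_yaml(path), path)


def read_cohort_spec(path: PathLike) -> CohortSpec:
    return _from_mapping(CohortSpec, _load_yaml(path), path)
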