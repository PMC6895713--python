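"""File formats: SWC/CSV traces, TIFF volumes with spacing sidecars,
ground-truth JSON, and the shared measurement-table CSV schema."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import SSTRecord
from .obliqueslice import VoxelVolume
from .synthgen import GroundTruthRecord
from .tracegeom import CenterlineSample, Polyline3D

MEASUREMENT_COLUMNS = [
    "bird_id",
    "sst_id",
    "point_index",
    "s_um",
    "d1_um",
    "d2_um",
    "circularity",
    "mean_diameter_um",
    "total_length_um",
]


# ---------------------------------------------------------------- volumes

def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    """Multi-page TIFF with ImageJ-style spacing metadata plus a YAML sidecar."""
    path = Path(path)
    sz, sy, sx = volume.spacing
    tifffile.imwrite(
        path,
        volume.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump({"voxel_spacing_um": {"z": sz, "y": sy, "x": sx}, "axes": "zyx"})
    )


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a TIFF stack; spacing from ImageJ metadata, YAML sidecar as fallback."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_tiff(tf)
    if spacing is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no voxel spacing in TIFF metadata and no sidecar {sidecar.name}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        sp = meta["voxel_spacing_um"]
        spacing = (float(sp["z"]), float(sp["y"]), float(sp["x"]))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    return VoxelVolume(data=data, spacing=spacing)


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        ij = tf.imagej_metadata or {}
        sz = float(ij["spacing"])
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
        return (sz, sy, sx)
    except (KeyError, TypeError, ZeroDivisionError):
        return None


# ----------------------------------------------------------------- traces

def write_trace_swc(path: str | Path, trace: Polyline3D, radius: float = 1.0) -> None:
    """Standard 7-column SWC: id, type, x, y, z, radius, parent."""
    lines = ["# id type x y z radius parent"]
    for i, (x, y, z) in enumerate(trace.points, start=1):
        parent = i - 1 if i > 1 else -1
        lines.append(f"{i} 0 {x:.6f} {y:.6f} {z:.6f} {radius:.3f} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_swc(path: str | Path) -> Polyline3D:
    pts = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 7:
            raise ValueError(f"{path}:{lineno}: SWC needs 7 columns, got {len(fields)}")
        pts.append([float(fields[2]), float(fields[3]), float(fields[4])])
    return Polyline3D(np.asarray(pts))


def write_trace_csv(path: str | Path, trace: Polyline3D) -> None:
    pd.DataFrame(trace.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> Polyline3D:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trace CSV is missing columns {missing}")
    return Polyline3D(df[["x", "y", "z"]].to_numpy(float))


def read_trace(path: str | Path) -> Polyline3D:
    path = Path(path)
    if path.suffix.lower() == ".swc":
        return read_trace_swc(path)
    return read_trace_csv(path)


def write_centerline_csv(path: str | Path, samples: list[CenterlineSample]) -> None:
    rows = [
        {
            "index": i,
            "x": s.position[0], "y": s.position[1], "z": s.position[2],
            "s_um": s.s,
            "tx": s.tangent[0], "ty": s.tangent[1], "tz": s.tangent[2],
        }
        for i, s in enumerate(samples)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------- ground truth / tables

def write_ground_truth(path: str | Path, gt: GroundTruthRecord) -> None:
    geom = gt.geometry
    payload = {
        "total_length_um": gt.total_length,
        "diameter_profile": list(geom.diameter_profile),
        "ellipticity": geom.ellipticity,
        "major_axis_orientation_rad": geom.major_axis_orientation,
        "n_granules": gt.n_granules,
        "centerline_xyz_um": gt.centerline.points.tolist(),
        "s_um": gt.s.tolist(),
        "d_mean_um": gt.d_mean.tolist(),
        "d1_um": gt.d1.tolist(),
        "d2_um": gt.d2.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def record_to_frame(record: SSTRecord) -> pd.DataFrame:
    rows = [
        {
            "bird_id": record.bird_id,
            "sst_id": record.sst_id,
            "point_index": i,
            "s_um": m.s,
            "d1_um": m.d1,
            "d2_um": m.d2,
            "circularity": m.circularity,
            "mean_diameter_um": m.mean_diameter,
            "total_length_um": record.total_length,
        }
        for i, m in enumerate(record.measurements)
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
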