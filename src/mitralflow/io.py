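"""Reading and writing the on-disk dataset layout.

A dataset directory holds:

* ``vel_x.nii.gz / vel_y.nii.gz / vel_z.nii.gz`` — one X*Y*Z*T float32
  volume per velocity component, cm/s;
* ``velocity_meta.json`` — VENC (cm/s) and frame times (ms);
* ``lv_mask.nii.gz`` — uint8 X*Y*Z*T LV mask;
* ``cine.nii.gz`` + ``cine_meta.json`` — long-axis image series and its
  plane pose / pixel spacing / frame times;
* ``landmarks.json`` — ``{"frame_index": int, "points_mm": [[x,y,z],[x,y,z]]}``;
* ``truth.json`` — phantom ground truth (synthetic datasets only).

Tracked planes, inflow curves and peak reports are written as JSON/CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    CineSeries,
    InflowCurve,
    LVMaskSeries,
    PeakPair,
    PlanePose,
    TrackedPlane,
    VelocityField,
)
from .phantom import Phantom

__all__ = [
    "save_velocity_field",
    "load_velocity_field",
    "save_lv_mask",
    "load_lv_mask",
    "save_cine",
    "load_cine",
    "save_landmarks",
    "load_landmarks",
    "save_phantom",
    "save_tracked_plane",
    "load_tracked_plane",
    "save_curve",
    "load_curve",
    "save_peaks",
]

PathLike = Union[str, Path]
_COMPONENTS = ("x", "y", "z")


def save_velocity_field(field: VelocityField, outdir: PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(_COMPONENTS):
        img = nib.Nifti1Image(field.data[c].astype(np.float32), field.affine)
        nib.save(img, outdir / f"vel_{name}.nii.gz")
    meta = {"venc": field.venc, "frame_times_ms": field.frame_times.tolist()}
    (outdir / "velocity_meta.json").write_text(json.dumps(meta, indent=2))


def load_velocity_field(indir: PathLike) -> VelocityField:
    indir = Path(indir)
    meta = json.loads((indir / "velocity_meta.json").read_text())
    comps = []
    affine = None
    for name in _COMPONENTS:
        img = nib.load(indir / f"vel_{name}.nii.gz")
        comps.append(np.asarray(img.dataobj, dtype=np.float32))
        affine = img.affine
    return VelocityField(
        data=np.stack(comps),
        affine=affine,
        frame_times=np.asarray(meta["frame_times_ms"], dtype=float),
        venc=float(meta["venc"]),
    )


def save_lv_mask(masks: LVMaskSeries, affine: np.ndarray, path: PathLike) -> None:
    vol = np.moveaxis(masks.masks.astype(np.uint8), 0, -1)  # (nx, ny, nz, nt)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def load_lv_mask(path: PathLike, provenance: str = "external_file") -> LVMaskSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj) > 0
    return LVMaskSeries(masks=np.moveaxis(vol, -1, 0), provenance=provenance)


def save_cine(cine: CineSeries, outdir: PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # (ni, nj, 1, nt) so standard viewers see a time series
    vol = np.moveaxis(cine.images.astype(np.float32), 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(vol, np.eye(4)), outdir / "cine.nii.gz")
    meta = {
        "origin_mm": cine.origin.tolist(),
        "axis_u": cine.axis_u.tolist(),
        "axis_v": cine.axis_v.tolist(),
        "pixel_spacing_mm": list(cine.pixel_spacing),
        "frame_times_ms": cine.frame_times.tolist(),
    }
    (outdir / "cine_meta.json").write_text(json.dumps(meta, indent=2))


def load_cine(indir: PathLike) -> CineSeries:
    indir = Path(indir)
    meta = json.loads((indir / "cine_meta.json").read_text())
    vol = np.asarray(nib.load(indir / "cine.nii.gz").dataobj, dtype=np.float32)
    images = np.moveaxis(vol[:, :, 0, :], -1, 0)
    return CineSeries(
        images=images,
        origin=np.asarray(meta["origin_mm"], float),
        axis_u=np.asarray(meta["axis_u"], float),
        axis_v=np.asarray(meta["axis_v"], float),
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        frame_times=np.asarray(meta["frame_times_ms"], float),
    )


def save_landmarks(landmarks: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(landmarks, indent=2))


def load_landmarks(path: PathLike) -> dict:
    lm = json.loads(Path(path).read_text())
    if "frame_index" not in lm or "points_mm" not in lm:
        raise ValueError("landmarks JSON must have 'frame_index' and 'points_mm'")
    return lm


def save_phantom(phantom: Phantom, outdir: PathLike) -> None:
    """Write a generated phantom as a complete dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_velocity_field(phantom.velocity, outdir)
    save_lv_mask(phantom.lv_mask, phantom.velocity.affine, outdir / "lv_mask.nii.gz")
    save_cine(phantom.cine, outdir)
    save_landmarks(phantom.init_landmarks, outdir / "landmarks.json")
    t = phantom.truth
    truth = {
        "true_peak_e": t.true_peak_e,
        "true_peak_a": t.true_peak_a,
        "true_ea_ratio": t.true_ea_ratio,
        "true_peak_flow_e": t.true_peak_flow_e,
        "true_peak_flow_a": t.true_peak_flow_a,
        "fused": bool(t.fused),
        "axial_attenuation_at_plane": t.axial_attenuation_at_plane,
        "annulus_trajectory_mm": t.annulus_trajectory.tolist(),
        "envelope_at_frames": t.envelope_at_frames.tolist(),
        "plane_speed_at_frames": t.plane_speed_at_frames.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def save_tracked_plane(plane: TrackedPlane, path: PathLike) -> None:
    payload = {
        "frame_times_ms": plane.frame_times.tolist(),
        "plane_velocity_cm_s": plane.plane_velocity.tolist(),
        "landmark_tracks_mm": plane.landmark_tracks.tolist(),
        "poses": [
            {
                "frame_index": p.frame_index,
                "origin_mm": p.origin.tolist(),
                "normal": p.normal.tolist(),
                "basis": p.basis.tolist(),
            }
            for p in plane.poses
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_tracked_plane(path: PathLike) -> TrackedPlane:
    payload = json.loads(Path(path).read_text())
    poses = [
        PlanePose(
            origin=np.asarray(p["origin_mm"], float),
            normal=np.asarray(p["normal"], float),
            basis=np.asarray(p["basis"], float),
            frame_index=int(p["frame_index"]),
        )
        for p in payload["poses"]
    ]
    return TrackedPlane(
        poses=poses,
        landmark_tracks=np.asarray(payload["landmark_tracks_mm"], float),
        plane_velocity=np.asarray(payload["plane_velocity_cm_s"], float),
        frame_times=np.asarray(payload["frame_times_ms"], float),
    )


def save_curve(curve: InflowCurve, path: PathLike) -> None:
    pd.DataFrame({"time_ms": curve.times, "value": curve.values}).to_csv(
        path, index=False
    )


def load_curve(path: PathLike, kind: str) -> InflowCurve:
    df = pd.read_csv(path)
    return InflowCurve(
        times=df["time_ms"].to_numpy(), values=df["value"].to_numpy(), kind=kind
    )


def save_peaks(peaks: PeakPair, path: PathLike) -> None:
    Path(path).write_text(json.dumps(asdict(peaks), indent=2))
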