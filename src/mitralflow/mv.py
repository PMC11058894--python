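"""Mitral-plane inflow quantification (MVvel and MVflow).

The velocity field is reformatted onto the tracked annulus plane, corrected
for the plane's own motion (velocity relative to the moving annulus),
median-filtered with a 3x3 kernel, and the inflow area segmented per frame.
MVvel takes the maximum through-plane velocity inside the inflow area;
MVflow integrates the through-plane velocity over the area.  E and A are
the two highest prominent peaks of the resulting curve inside the diastolic
window; curves with fewer than two discernible peaks are flagged as fused
(monophasic inflow), mirroring the clinical exclusion of such datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.signal import peak_prominences

from .datatypes import (
    InflowCurve,
    PeakPair,
    PlaneVelocityMap,
    TrackedPlane,
    VelocityField,
)

__all__ = [
    "reformat_velocity",
    "correct_for_plane_motion",
    "median_filter_map",
    "segment_inflow_area",
    "max_velocity_curve",
    "flow_rate_curve",
    "detect_ea_peaks",
    "MVResult",
    "mvvel_ea",
    "mvflow_ea",
]


def reformat_velocity(
    field: VelocityField,
    plane: TrackedPlane,
    grid_spacing: float = 1.0,
    grid_extent: float = 50.0,
) -> PlaneVelocityMap:
    """Resample through-plane velocity on the tracked 2D plane.

    Per frame, a square grid of ``grid_extent`` mm at ``grid_spacing`` mm,
    centred on the annulus midpoint and spanned by the plane basis, is
    sampled by trilinear interpolation of the three velocity components;
    each sample is projected onto the frame's plane normal (positive toward
    the apex).  Grid points outside the velocity volume are zero and marked
    invalid.
    """
    if plane.n_frames != field.n_frames:
        raise ValueError(
            f"plane has {plane.n_frames} frames but field has {field.n_frames}"
        )
    if grid_spacing <= 0 or grid_extent <= 0:
        raise ValueError("grid_spacing and grid_extent must be positive")
    half = grid_extent / 2.0
    offsets = np.arange(-half, half + grid_spacing / 2, grid_spacing)
    n = len(offsets)
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    inv_affine = np.linalg.inv(field.affine)
    shape = np.array(field.spatial_shape)

    values = np.zeros((field.n_frames, n, n))
    valid = np.zeros((field.n_frames, n, n), dtype=bool)
    data = field.data.astype(float)
    for t, pose in enumerate(plane.poses):
        pts = (
            pose.origin[None, :]
            + uu.ravel()[:, None] * pose.basis[0]
            + vv.ravel()[:, None] * pose.basis[1]
        )
        vox = (np.c_[pts, np.ones(len(pts))] @ inv_affine.T)[:, :3]
        inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
        coords = vox.T
        comps = [
            ndimage.map_coordinates(data[c, ..., t], coords, order=1, cval=0.0)
            for c in range(3)
        ]
        v = np.stack(comps, axis=1) @ pose.normal
        v[~inside] = 0.0
        values[t] = v.reshape(n, n)
        valid[t] = inside.reshape(n, n)
    return PlaneVelocityMap(
        values=values,
        valid=valid,
        grid_spacing=grid_spacing,
        grid_extent=grid_extent,
        plane=plane,
        frame_times=field.frame_times,
    )


def correct_for_plane_motion(
    vmap: PlaneVelocityMap, plane_velocity: Optional[np.ndarray] = None
) -> PlaneVelocityMap:
    """Subtract the plane's own normal velocity from every grid value,
    yielding velocity relative to the moving annulus."""
    pv = vmap.plane.plane_velocity if plane_velocity is None else np.asarray(plane_velocity, float)
    if len(pv) != vmap.n_frames:
        raise ValueError("plane_velocity length must match the number of frames")
    out = vmap.copy()
    out.values = out.values - pv[:, None, None]
    out.values[~out.valid] = 0.0
    return out


def median_filter_map(vmap: PlaneVelocityMap) -> PlaneVelocityMap:
    """3x3 spatial median filter per frame, borders replicated."""
    out = vmap.copy()
    for t in range(out.n_frames):
        out.values[t] = ndimage.median_filter(out.values[t], size=3, mode="nearest")
    return out


def segment_inflow_area(
    vmap: PlaneVelocityMap,
    velocity_floor: float = 5.0,
    relative_threshold: float = 0.15,
) -> np.ndarray:
    """Segment the forward-inflow area per frame.

    Threshold at ``max(velocity_floor, relative_threshold * frame max
    positive velocity)``, keep the connected component containing (or
    nearest to) the grid centre, and fill holes.  Frames with no forward
    flow yield an empty mask.  Returns the (nt, n, n) boolean masks and
    stores them on the map.
    """
    nt, n, _ = vmap.values.shape
    center = (n // 2, n // 2)
    masks = np.zeros_like(vmap.values, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)
    for t in range(nt):
        frame = np.where(vmap.valid[t], vmap.values[t], 0.0)
        fmax = frame.max()
        if fmax <= 0:
            continue
        thr = max(velocity_floor, relative_threshold * fmax)
        binary = (frame >= thr) & vmap.valid[t]
        if not binary.any():
            continue
        labels, n_lab = ndimage.label(binary, structure=structure)
        target = labels[center]
        if target == 0:
            # nearest component to the grid centre
            ii, jj = np.nonzero(binary)
            d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2
            target = labels[ii[np.argmin(d2)], jj[np.argmin(d2)]]
        comp = labels == target
        masks[t] = ndimage.binary_fill_holes(comp) & vmap.valid[t]
    vmap.inflow_masks = masks
    return masks


def _require_masks(vmap: PlaneVelocityMap) -> np.ndarray:
    if vmap.inflow_masks is None:
        raise ValueError("run segment_inflow_area first (inflow_masks missing)")
    return vmap.inflow_masks


def max_velocity_curve(vmap: PlaneVelocityMap) -> InflowCurve:
    """Per-frame maximum through-plane velocity inside the inflow mask
    (0 on empty-mask frames)."""
    masks = _require_masks(vmap)
    values = np.array(
        [
            vmap.values[t][masks[t]].max() if masks[t].any() else 0.0
            for t in range(vmap.n_frames)
        ]
    )
    return InflowCurve(times=vmap.frame_times, values=values, kind="max_velocity")


def flow_rate_curve(vmap: PlaneVelocityMap) -> InflowCurve:
    """Per-frame volumetric flow rate (mL/s): through-plane velocity summed
    over the inflow mask times pixel area."""
    masks = _require_masks(vmap)
    pixel_area_cm2 = (vmap.grid_spacing / 10.0) ** 2
    values = np.array(
        [vmap.values[t][masks[t]].sum() * pixel_area_cm2 for t in range(vmap.n_frames)]
    )
    return InflowCurve(times=vmap.frame_times, values=values, kind="flow_rate")


# ---------------------------------------------------------------------------
# E/A peak detection
# ---------------------------------------------------------------------------

def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus collapse to their first
    sample; window endpoints are not maxima."""
    n = len(values)
    maxima = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1
    return maxima


def detect_ea_peaks(
    curve: InflowCurve,
    diastole_window: Union[str, tuple[float, float]] = "auto",
    window_start_frac: float = 0.35,
    prominence_frac: float = 0.10,
    cycle_length: Optional[float] = None,
) -> PeakPair:
    """Select the E (earlier) and A (later) peaks of a diastolic inflow curve.

    The curve is restricted to the diastolic window — "auto" starts at the
    first positive sample after cycle fraction ``window_start_frac`` (the
    peaks lie between end-systole and end-diastole) and runs to the last
    frame.  Local maxima with prominence below ``prominence_frac`` of the
    window maximum are discarded; of the rest, the two largest are E and A
    in time order.  Fewer than two surviving maxima flags the curve as
    fused (monophasic inflow).  Ties in value are broken by greater
    prominence, then earlier time.
    """
    times, values = curve.times, curve.values
    if cycle_length is None:
        cycle_length = times[-1] + float(np.median(np.diff(times)))

    if isinstance(diastole_window, str):
        if diastole_window != "auto":
            raise ValueError("diastole_window must be a (t0, t1) tuple or 'auto'")
        candidates = np.flatnonzero(
            (times > window_start_frac * cycle_length) & (values > 0)
        )
        if len(candidates) == 0:
            warnings.warn(
                "no positive inflow after the systolic window; flagging as fused",
                RuntimeWarning,
                stacklevel=2,
            )
            t0 = window_start_frac * cycle_length
            return PeakPair(None, None, None, None, None, True, (t0, float(times[-1])))
        window = (float(times[candidates[0]]), float(times[-1]))
    else:
        window = (float(diastole_window[0]), float(diastole_window[1]))

    sel = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    if len(sel) < 5:
        raise ValueError("need at least 5 samples inside the diastole window")
    w_t = times[sel]
    w_v = values[sel]

    def fused_pair() -> PeakPair:
        warnings.warn(
            "fewer than two discernible inflow peaks (monophasic inflow)",
            RuntimeWarning,
            stacklevel=3,
        )
        return PeakPair(None, None, None, None, None, True, window)

    wmax = w_v.max()
    if wmax <= w_v.min():  # flat window
        return fused_pair()
    maxima = _local_maxima(w_v)
    if not maxima:
        return fused_pair()
    proms = peak_prominences(w_v, maxima)[0]
    floor = prominence_frac * wmax
    kept = [(i, p) for i, p in zip(maxima, proms) if p >= floor]
    if len(kept) < 2:
        return fused_pair()
    kept.sort(key=lambda ip: (-w_v[ip[0]], -ip[1], w_t[ip[0]]))
    two = sorted(kept[:2], key=lambda ip: w_t[ip[0]])
    (ie, _), (ia, _) = two
    e_value, a_value = float(w_v[ie]), float(w_v[ia])
    return PeakPair(
        e_value=e_value,
        a_value=a_value,
        e_time=float(w_t[ie]),
        a_time=float(w_t[ia]),
        ea_ratio=e_value / a_value,
        fused=False,
        diastole_window=window,
    )


# ---------------------------------------------------------------------------
# End-to-end MV pipelines
# ---------------------------------------------------------------------------

@dataclass
class MVResult:
    """Output of one mitral-plane method: the processed plane map, the
    inflow curve, and the detected peaks."""

    velocity_map: PlaneVelocityMap
    curve: InflowCurve
    peaks: PeakPair


def _mv_pipeline(
    field: VelocityField,
    plane: TrackedPlane,
    grid_spacing: float,
    grid_extent: float,
    correct_motion: bool,
) -> PlaneVelocityMap:
    vmap = reformat_velocity(field, plane, grid_spacing, grid_extent)
    if correct_motion:
        vmap = correct_for_plane_motion(vmap)
    vmap = median_filter_map(vmap)
    segment_inflow_area(vmap)
    return vmap


def mvvel_ea(
    field: VelocityField,
    plane: TrackedPlane,
    diastole_window: Union[str, tuple[float, float]] = "auto",
    grid_spacing: float = 1.0,
    grid_extent: float = 50.0,
    correct_motion: bool = True,
    cycle_length: Optional[float] = None,
) -> MVResult:
    """MVvel: E/A from the maximum inflow velocity at the tracked plane."""
    vmap = _mv_pipeline(field, plane, grid_spacing, grid_extent, correct_motion)
    curve = max_velocity_curve(vmap)
    peaks = detect_ea_peaks(curve, diastole_window, cycle_length=cycle_length)
    return MVResult(velocity_map=vmap, curve=curve, peaks=peaks)


def mvflow_ea(
    field: VelocityField,
    plane: TrackedPlane,
    diastole_window: Union[str, tuple[float, float]] = "auto",
    grid_spacing: float = 1.0,
    grid_extent: float = 50.0,
    correct_motion: bool = True,
    cycle_length: Optional[float] = None,
) -> MVResult:
    """MVflow: E/A from the volumetric inflow rate through the tracked plane."""
    vmap = _mv_pipeline(field, plane, grid_spacing, grid_extent, correct_motion)
    curve = flow_rate_curve(vmap)
    peaks = detect_ea_peaks(curve, diastole_window, cycle_length=cycle_length)
    return MVResult(velocity_map=vmap, curve=curve, peaks=peaks)
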