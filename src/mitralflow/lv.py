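"""LV-mask inflow quantification (LVvel).

The fully automatic method: per frame, the maximum blood speed anywhere
inside a left-ventricular segmentation mask, after 3x3x3 median filtering
of the speed volume.  Unconstrained to the mitral plane, it captures the
vena contracta wherever it sits, so its peaks bound the mitral-plane
method's from above.  E and A peaks are selected from the per-frame
maximum-speed curve restricted to diastole, exactly as for the
mitral-plane methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .datatypes import InflowCurve, LVMaskSeries, PeakPair, VelocityField
from .mv import detect_ea_peaks

__all__ = [
    "speed_volume",
    "median_filter_speed",
    "lv_max_speed_curve",
    "LVResult",
    "lvvel_ea",
]


def speed_volume(field: VelocityField) -> np.ndarray:
    """Euclidean speed per voxel per frame: sqrt(vx^2 + vy^2 + vz^2), cm/s."""
    return np.sqrt(np.sum(field.data.astype(float) ** 2, axis=0))


def median_filter_speed(speed: np.ndarray) -> np.ndarray:
    """3x3x3 spatial median per frame, borders replicated."""
    speed = np.asarray(speed, dtype=float)
    if speed.ndim != 4:
        raise ValueError("speed must be a 4D (nx, ny, nz, nt) volume")
    out = np.empty_like(speed)
    for t in range(speed.shape[-1]):
        out[..., t] = ndimage.median_filter(speed[..., t], size=3, mode="nearest")
    return out


def lv_max_speed_curve(
    speed: np.ndarray, masks: LVMaskSeries, frame_times: np.ndarray
) -> InflowCurve:
    """Per-frame maximum of the (filtered) speed inside the LV mask."""
    speed = np.asarray(speed, dtype=float)
    if speed.shape[:3] != masks.masks.shape[1:] or speed.shape[-1] != masks.n_frames:
        raise ValueError("speed volume and mask series shapes do not match")
    values = np.empty(masks.n_frames)
    for t in range(masks.n_frames):
        m = masks.masks[t]
        if not m.any():
            raise ValueError(f"empty LV mask at frame {t}")
        values[t] = speed[..., t][m].max()
    return InflowCurve(times=frame_times, values=values, kind="lv_max_speed")


@dataclass
class LVResult:
    """Output of the LVvel method."""

    curve: InflowCurve
    peaks: PeakPair


def lvvel_ea(
    field: VelocityField,
    masks: LVMaskSeries,
    diastole_window: Union[str, tuple[float, float]] = "auto",
    filter_order: str = "filter_then_mask",
    cycle_length: Optional[float] = None,
) -> LVResult:
    """LVvel: E/A from the maximum speed anywhere within the LV mask.

    ``filter_order`` selects whether the 3x3x3 median runs on the full
    speed volume before masking (default; avoids mask-boundary artifacts)
    or on the speed volume zeroed outside the mask.
    """
    speed = speed_volume(field)
    if filter_order == "filter_then_mask":
        filtered = median_filter_speed(speed)
    elif filter_order == "mask_then_filter":
        masked = np.where(np.moveaxis(masks.masks, 0, -1), speed, 0.0)
        filtered = median_filter_speed(masked)
    else:
        raise ValueError("filter_order must be 'filter_then_mask' or 'mask_then_filter'")
    curve = lv_max_speed_curve(filtered, masks, field.frame_times)
    peaks = detect_ea_peaks(curve, diastole_window, cycle_length=cycle_length)
    return LVResult(curve=curve, peaks=peaks)
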