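"""Velocity aliasing (phase-wrap) and background phase-offset correction.

Phase-contrast velocities alias when the true speed exceeds the
velocity-encoding limit (VENC): the stored value wraps by multiples of
2*VENC.  :func:`unwrap_velocity` removes single and multiple wraps by
temporal continuity, anchored at frame 0 (assumed alias-free — in cardiac
data frame 0 is end-diastole, where transmitral velocities are near zero).

Eddy-current background phase offsets are quasi-static, spatially smooth
velocity errors; :func:`correct_background_phase` fits a low-order spatial
polynomial to the time-averaged velocity of stationary tissue and subtracts
it from every frame.
"""

from __future__ import annotations

import itertools
import logging
from typing import Union

import numpy as np

from .datatypes import BackgroundModel, VelocityField

__all__ = ["unwrap_velocity", "correct_background_phase", "wrap_velocity"]

logger = logging.getLogger(__name__)


def wrap_velocity(values: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into [-venc, +venc) by modular arithmetic."""
    return (np.asarray(values) + venc) % (2 * venc) - venc


def unwrap_velocity(field: VelocityField) -> VelocityField:
    """Temporally unwrap aliased velocities.

    For every voxel and component, each frame t >= 1 is shifted by the
    integer multiple of 2*VENC that brings it closest to the (already
    unwrapped) previous frame.  Output values may exceed +/-VENC.  The
    transform is idempotent on fields whose frame-to-frame differences are
    all below VENC.
    """
    out = field.data.astype(float, copy=True)
    venc = field.venc
    n_corrected = 0
    for t in range(1, out.shape[-1]):
        k = np.round((out[..., t - 1] - out[..., t]) / (2 * venc))
        n_corrected += int(np.count_nonzero(k))
        out[..., t] += 2 * venc * k
    logger.info("unwrap_velocity: corrected %d voxel-frames", n_corrected)
    return VelocityField(
        data=out, affine=field.affine, frame_times=field.frame_times, venc=venc
    )


def _monomial_exponents(order: int) -> list[tuple[int, int, int]]:
    return [
        (i, j, k)
        for i, j, k in itertools.product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]


def _auto_static_mask(
    field: VelocityField, mean_thresh: float, sd_thresh: float
) -> np.ndarray:
    speed = np.sqrt(np.sum(field.data.astype(float) ** 2, axis=0))  # (nx,ny,nz,nt)
    return (speed.mean(axis=-1) < mean_thresh) & (speed.std(axis=-1) < sd_thresh)


def correct_background_phase(
    field: VelocityField,
    static_mask: Union[np.ndarray, str] = "auto",
    order: int = 1,
    per_frame: bool = False,
    auto_mean_thresh: float = 2.0,
    auto_sd_thresh: float = 2.0,
) -> tuple[VelocityField, BackgroundModel]:
    """Fit and subtract a spatial polynomial background offset.

    Parameters
    ----------
    static_mask : ndarray or "auto"
        Binary volume of stationary-tissue voxels used for the fit.  With
        "auto", voxels whose temporal-mean speed and temporal speed SD both
        fall below the thresholds (cm/s) are used.
    order : int
        Spatial polynomial order (0-2), fitted per velocity component on
        world-mm coordinates by least squares.
    per_frame : bool
        Fit each timeframe separately instead of the time-averaged field
        (background offsets are quasi-static, so the default fits the mean).

    Returns the corrected field and the fitted :class:`BackgroundModel`
    (coefficients of the time-averaged fit).
    """
    if not 0 <= order <= 2:
        raise ValueError("polynomial order must be 0, 1 or 2")
    if isinstance(static_mask, str):
        if static_mask != "auto":
            raise ValueError("static_mask must be an array or 'auto'")
        mask = _auto_static_mask(field, auto_mean_thresh, auto_sd_thresh)
    else:
        mask = np.asarray(static_mask, dtype=bool)
        if mask.shape != field.spatial_shape:
            raise ValueError("static mask shape must match the velocity grid")

    exponents = _monomial_exponents(order)
    n_coef = len(exponents)
    n_static = int(mask.sum())
    if n_static < n_coef:
        raise ValueError(
            f"static mask has {n_static} voxels, fewer than the {n_coef} "
            "polynomial coefficients"
        )

    ijk = np.argwhere(mask)
    world = (np.c_[ijk, np.ones(len(ijk))] @ field.affine.T)[:, :3]
    design = np.stack(
        [world[:, 0] ** i * world[:, 1] ** j * world[:, 2] ** k for i, j, k in exponents],
        axis=1,
    )

    # full-grid design for subtraction
    nx, ny, nz = field.spatial_shape
    all_ijk = np.indices((nx, ny, nz)).reshape(3, -1).T
    all_world = (np.c_[all_ijk, np.ones(len(all_ijk))] @ field.affine.T)[:, :3]
    all_design = np.stack(
        [
            all_world[:, 0] ** i * all_world[:, 1] ** j * all_world[:, 2] ** k
            for i, j, k in exponents
        ],
        axis=1,
    )

    out = field.data.astype(float, copy=True)
    mean_coeffs = np.zeros((3, n_coef))
    for c in range(3):
        if per_frame:
            for t in range(field.n_frames):
                target = out[c][..., t][mask]
                coef, *_ = np.linalg.lstsq(design, target, rcond=None)
                out[c][..., t] -= (all_design @ coef).reshape(nx, ny, nz)
            mean_target = field.data[c].astype(float).mean(axis=-1)[mask]
            mean_coeffs[c], *_ = np.linalg.lstsq(design, mean_target, rcond=None)
        else:
            target = out[c].mean(axis=-1)[mask]
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            mean_coeffs[c] = coef
            out[c] -= (all_design @ coef).reshape(nx, ny, nz)[..., None]

    logger.info(
        "correct_background_phase: order %d fit on %d static voxels", order, n_static
    )
    model = BackgroundModel(
        polynomial_order=order,
        exponents=exponents,
        coefficients=mean_coeffs,
        static_mask=mask,
    )
    corrected = VelocityField(
        data=out, affine=field.affine, frame_times=field.frame_times, venc=field.venc
    )
    return corrected, model
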