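"""Core data containers shared by every quantification method.

Conventions
-----------
* World coordinates are right-handed millimetres, given by the NIfTI affine;
  the left-ventricular long axis points along world +z by default (base at
  low z, apex at high z).
* Velocities are in cm/s.  Through-plane velocities are signed positive in
  the direction annulus -> apex, so diastolic transmitral inflow is positive.
* Times are in milliseconds from the start of the cardiac cycle (R wave).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VelocityField",
    "CineSeries",
    "PlanePose",
    "TrackedPlane",
    "PlaneVelocityMap",
    "InflowCurve",
    "PeakPair",
    "LVMaskSeries",
    "BackgroundModel",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must contain only finite values")
    return arr


@dataclass
class VelocityField:
    """Time-resolved three-component voxel velocity data.

    Parameters
    ----------
    data : ndarray, shape (3, nx, ny, nz, nt)
        Velocity components along the world x/y/z axes, cm/s.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform shared by all three components.
    frame_times : ndarray, shape (nt,)
        Time of each reconstructed frame, ms, strictly increasing.
    venc : float
        Velocity-encoding limit, cm/s.  Stored phase velocities alias
        (wrap) beyond +/- venc.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_times: np.ndarray
    venc: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5 or self.data.shape[0] != 3:
            raise ValueError(
                "data must have shape (3, nx, ny, nz, nt); got "
                f"{self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity data must be finite")
        self.affine = _as_float_array(self.affine, "affine")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.frame_times = _as_float_array(self.frame_times, "frame_times")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.data.shape[-1]:
            raise ValueError("frame_times length must equal the number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.venc <= 0:
            raise ValueError("venc must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[pts, np.ones(len(pts))]
        return (homog @ inv.T)[:, :3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[idx, np.ones(len(idx))]
        return (homog @ self.affine.T)[:, :3]

    def copy(self) -> "VelocityField":
        return replace(self, data=self.data.copy())


@dataclass
class CineSeries:
    """Long-axis (three-chamber-like) image series used for valve tracking.

    Images are indexed ``images[t, i, j]`` where *i* runs along ``axis_u``
    and *j* along ``axis_v``; the pose maps pixel indices to world mm.
    """

    images: np.ndarray  # (nt, ni, nj)
    origin: np.ndarray  # world mm of pixel (0, 0)
    axis_u: np.ndarray  # unit vector of the i axis
    axis_v: np.ndarray  # unit vector of the j axis
    pixel_spacing: tuple[float, float]  # mm per pixel along (u, v)
    frame_times: np.ndarray  # ms

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (nt, ni, nj)")
        self.origin = _as_float_array(self.origin, "origin")
        self.axis_u = _as_float_array(self.axis_u, "axis_u")
        self.axis_v = _as_float_array(self.axis_v, "axis_v")
        self.axis_u = self.axis_u / np.linalg.norm(self.axis_u)
        self.axis_v = self.axis_v / np.linalg.norm(self.axis_v)
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        self.frame_times = _as_float_array(self.frame_times, "frame_times")
        if len(self.frame_times) != self.images.shape[0]:
            raise ValueError("frame count mismatch between images and frame_times")

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    @property
    def through_plane(self) -> np.ndarray:
        """Unit normal of the imaging plane (u x v)."""
        n = np.cross(self.axis_u, self.axis_v)
        return n / np.linalg.norm(n)

    def pixel_to_world(self, uv: np.ndarray) -> np.ndarray:
        """Map pixel coordinates (..., 2) to world mm."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        du, dv = self.pixel_spacing
        return (
            self.origin
            + uv[:, [0]] * du * self.axis_u
            + uv[:, [1]] * dv * self.axis_v
        )

    def world_to_pixel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) - self.origin
        du, dv = self.pixel_spacing
        return np.c_[pts @ self.axis_u / du, pts @ self.axis_v / dv]


@dataclass
class PlanePose:
    """Pose of the mitral annulus plane at one timeframe."""

    origin: np.ndarray  # annulus midpoint, world mm
    normal: np.ndarray  # unit, oriented annulus -> apex
    basis: np.ndarray  # (2, 3) orthonormal in-plane vectors
    frame_index: int

    def __post_init__(self) -> None:
        self.origin = _as_float_array(self.origin, "origin")
        self.normal = _as_float_array(self.normal, "normal")
        self.basis = _as_float_array(self.basis, "basis")
        if abs(np.linalg.norm(self.normal) - 1) > 1e-8:
            raise ValueError("normal must be a unit vector")
        if self.basis.shape != (2, 3):
            raise ValueError("basis must be (2, 3)")
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(2), atol=1e-8):
            raise ValueError("basis must be orthonormal")
        if np.max(np.abs(self.basis @ self.normal)) > 1e-8:
            raise ValueError("basis must be orthogonal to the normal")


@dataclass
class TrackedPlane:
    """Mitral annulus plane pose per frame plus its own normal velocity."""

    poses: list[PlanePose]
    landmark_tracks: np.ndarray  # (2, nt, 3), world mm
    plane_velocity: np.ndarray  # signed speed of origin along normal, cm/s
    frame_times: np.ndarray  # ms

    #: maximum allowed angle (degrees) between consecutive normals
    MAX_NORMAL_STEP_DEG = 30.0

    def __post_init__(self) -> None:
        self.landmark_tracks = _as_float_array(self.landmark_tracks, "landmark_tracks")
        self.plane_velocity = _as_float_array(self.plane_velocity, "plane_velocity")
        self.frame_times = _as_float_array(self.frame_times, "frame_times")
        nt = len(self.poses)
        if self.landmark_tracks.shape != (2, nt, 3):
            raise ValueError("landmark_tracks must be (2, n_frames, 3)")
        if len(self.plane_velocity) != nt or len(self.frame_times) != nt:
            raise ValueError("per-frame arrays must match the number of poses")
        normals = self.normals
        cosang = np.clip(np.sum(normals * np.roll(normals, -1, axis=0), axis=1), -1, 1)
        max_step = np.degrees(np.arccos(cosang)).max() if nt > 1 else 0.0
        if max_step >= self.MAX_NORMAL_STEP_DEG:
            warnings.warn(
                f"plane normal jumps by {max_step:.1f} deg between frames; "
                "tracking may be unreliable",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return len(self.poses)

    @property
    def origins(self) -> np.ndarray:
        return np.array([p.origin for p in self.poses])

    @property
    def normals(self) -> np.ndarray:
        return np.array([p.normal for p in self.poses])


@dataclass
class PlaneVelocityMap:
    """Through-plane velocity resampled on the tracked 2D plane.

    ``values[t, i, j]`` is the through-plane velocity (cm/s, positive toward
    the apex) at in-plane offset ``(u_i, v_j)`` from the annulus midpoint.
    ``valid`` marks grid points whose world position fell inside the velocity
    volume; outside samples are zero and excluded from inflow masks.
    """

    values: np.ndarray  # (nt, n, n) cm/s
    valid: np.ndarray  # (nt, n, n) bool
    grid_spacing: float  # mm
    grid_extent: float  # mm
    plane: TrackedPlane
    frame_times: np.ndarray  # ms
    inflow_masks: Optional[np.ndarray] = None  # (nt, n, n) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("plane velocity values must be finite")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match values shape")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.inflow_masks is not None:
            self.inflow_masks = np.asarray(self.inflow_masks, dtype=bool)
            if self.inflow_masks.shape != self.values.shape:
                raise ValueError("inflow_masks must match values shape")
            if np.any(self.inflow_masks & ~self.valid):
                raise ValueError("inflow masks must be subsets of the valid grid")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "PlaneVelocityMap":
        return replace(
            self,
            values=self.values.copy(),
            valid=self.valid.copy(),
            inflow_masks=None if self.inflow_masks is None else self.inflow_masks.copy(),
        )


CURVE_KINDS = ("max_velocity", "flow_rate", "lv_max_speed")


@dataclass
class InflowCurve:
    """A per-frame scalar summary of transmitral inflow.

    ``kind`` is one of ``max_velocity`` (cm/s), ``flow_rate`` (mL/s, may be
    negative on systolic/regurgitant frames) or ``lv_max_speed`` (cm/s).
    """

    times: np.ndarray  # ms
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}")


@dataclass
class PeakPair:
    """Detected E and A peaks of a diastolic inflow curve.

    When ``fused`` is True (monophasic inflow: the E and A waves cannot be
    separately discerned) the peak fields are None and no E/A ratio is
    reported, mirroring the clinical exclusion of such datasets.
    """

    e_value: Optional[float]
    a_value: Optional[float]
    e_time: Optional[float]
    a_time: Optional[float]
    ea_ratio: Optional[float]
    fused: bool
    diastole_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.fused:
            if any(
                v is not None
                for v in (self.e_value, self.a_value, self.e_time, self.a_time, self.ea_ratio)
            ):
                raise ValueError("fused PeakPair must leave the peak fields unset")
            return
        t0, t1 = self.diastole_window
        if not (t0 <= self.e_time < self.a_time <= t1):
            raise ValueError("require e_time < a_time inside the diastole window")
        if not np.isclose(self.ea_ratio, self.e_value / self.a_value):
            raise ValueError("ea_ratio must equal e_value / a_value")


@dataclass
class LVMaskSeries:
    """Binary left-ventricular masks aligned to the velocity grid."""

    masks: np.ndarray  # (nt, nx, ny, nz) bool
    provenance: str = "external_file"  # or "phantom_truth"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 4:
            raise ValueError("masks must be (nt, nx, ny, nz)")
        empty = ~self.masks.any(axis=(1, 2, 3))
        if empty.any():
            raise ValueError(
                f"LV mask is empty at frame(s) {np.flatnonzero(empty).tolist()}"
            )

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class BackgroundModel:
    """Fitted spatial polynomial of the stationary-tissue velocity offset.

    ``coefficients[c]`` holds, for velocity component *c*, one coefficient
    per monomial in ``exponents`` (evaluated on world-mm coordinates, cm/s).
    """

    polynomial_order: int
    exponents: list[tuple[int, int, int]]
    coefficients: np.ndarray  # (3, n_terms)
    static_mask: np.ndarray  # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        if not 0 <= self.polynomial_order <= 2:
            raise ValueError("polynomial order must be 0, 1 or 2")
        self.coefficients = _as_float_array(self.coefficients, "coefficients")
        self.static_mask = np.asarray(self.static_mask, dtype=bool)
        if not self.static_mask.any():
            raise ValueError("static mask must be non-empty")

    def evaluate(self, points_mm: np.ndarray) -> np.ndarray:
        """Evaluate the per-component offset at world points (..., 3) -> (n, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        design = np.stack(
            [pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k for i, j, k in self.exponents],
            axis=1,
        )
        return design @ self.coefficients.T
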