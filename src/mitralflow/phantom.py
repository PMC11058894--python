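"""Synthetic 4D cardiac flow phantom with known transmitral E/A ground truth.

The phantom emulates the statistical and physiological structure that the
mitral-plane and LV-mask quantification methods assume:

* a transmitral inflow jet crossing a mitral annulus plane that translates
  along the LV long axis over the cardiac cycle,
* a temporal inflow envelope that is the sum of a raised-cosine E pulse and
  a raised-cosine A pulse (which may merge into a single, "fused" diastolic
  peak when the pulses overlap),
* a vena contracta — the spatial speed maximum of the jet — located a few
  millimetres apical to the annulus plane, where the speed equals the
  envelope exactly,
* a systolic outflow jet inside the LV mask (so LV-based peak search must be
  restricted to diastole),
* optional Gaussian velocity noise and optional velocity aliasing (values
  wrapped into [-VENC, +VENC)),
* a long-axis cine series rendering the two annulus landmarks as bright,
  trackable blobs, and a ground-truth LV mask per frame.

The jet cross-section is a plug-flow core with a Gaussian shoulder; the
axial profile is flat toward the apex and decays as a Gaussian toward the
annulus.  A plug core of about 1.5 voxels keeps the recorded true peak
invariant under the 3x3(x3) median filters that the quantification methods
apply, so phantom-recovery errors measure the methods, not the sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

from .datatypes import CineSeries, LVMaskSeries, VelocityField

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "Phantom",
    "generate_phantom",
    "inflow_envelope",
    "effective_jet_area_mm2",
    "MethodModel",
    "make_paired_measurements",
    "DEFAULT_METHOD_MODELS",
]


@dataclass
class PhantomParams:
    """Acquisition and physiology parameters of the synthetic phantom.

    Defaults follow a typical clinical 4D-flow protocol (VENC 120 cm/s,
    ~2.8 mm isotropic voxels, 30 reconstructed frames at ~33 ms for a
    1000 ms cycle, i.e. ~53 ms acquired temporal resolution after view
    sharing) and an elderly-cohort physiology (peak E 60 cm/s, peak A
    50 cm/s, E/A 1.2, 12 mm annular excursion).  The E and A peak times
    default to exact sample times of the 30-frame grid so that temporal
    discretization does not alias into method error.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 50)
    voxel_size: float = 2.8  # mm, isotropic
    n_frames: int = 30
    cycle_length: float = 1000.0  # ms
    venc: float = 120.0  # cm/s

    # inflow physiology
    peak_e_velocity: float = 60.0  # cm/s at the vena contracta
    peak_a_velocity: float = 50.0
    e_peak_time_frac: float = 13.0 / 30.0
    a_peak_time_frac: float = 26.0 / 30.0
    e_width: float = 130.0  # raised-cosine half-width, ms
    a_width: float = 110.0

    # jet geometry
    jet_radius: float = 6.0  # Gaussian shoulder sigma, mm
    jet_core_radius: float = 4.5  # plug-flow core radius, mm
    vena_contracta_offset: float = 5.0  # mm apical to the annulus plane
    axial_sigma_down: float = 7.5  # Gaussian decay toward the annulus, mm
    axial_core_up: float = 4.0  # flat axial core toward the apex, mm
    axial_sigma_up: float = 8.0

    # anatomy / motion
    annulus_z0: float = 40.0  # annulus plane z at end-diastole, mm
    annulus_excursion: float = 12.0  # peak longitudinal displacement, mm
    annulus_radius: float = 19.0  # mm, sets the cine landmark separation
    lv_radius: float = 30.0  # mm
    lv_length: float = 85.0  # annulus-to-apex distance, mm

    # systolic outflow jet (inside the LV mask)
    systolic_peak_velocity: float = 90.0  # cm/s, directed base-ward
    systolic_peak_time_frac: float = 0.12
    systolic_width: float = 110.0  # ms
    systolic_offset: float = -15.0  # jet axis offset along x from LV axis, mm

    # measurement imperfections
    noise_sd: float = 0.0  # cm/s per velocity component
    inject_aliasing: bool = False
    cine_pixel_spacing: float = 1.0  # mm
    cine_noise_sd: float = 0.0  # image intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if not (0 < self.e_peak_time_frac < self.a_peak_time_frac < 1):
            raise ValueError(
                "peak times must satisfy 0 < e_peak_time_frac < a_peak_time_frac < 1"
            )
        if min(self.peak_e_velocity, self.peak_a_velocity) < 0:
            raise ValueError("peak velocities must be non-negative")
        if self.jet_radius <= self.voxel_size:
            raise ValueError("jet_radius must exceed the voxel size")
        if min(self.e_width, self.a_width) <= 0:
            raise ValueError("pulse widths must be positive")
        if self.noise_sd < 0 or self.cine_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.vena_contracta_offset < 0:
            raise ValueError("vena_contracta_offset must be non-negative")
        # the jet (core + 3 sigma shoulder) must fit inside the grid cross-section
        half_extent = (min(self.grid_shape[:2]) - 1) * self.voxel_size / 2.0
        if self.jet_core_radius + 3 * self.jet_radius > half_extent:
            raise ValueError("jet exceeds the grid cross-section")
        apex_z = self.annulus_z0 + self.lv_length
        if apex_z > (self.grid_shape[2] - 1) * self.voxel_size:
            raise ValueError("LV long axis exceeds the grid in z")

    # --- derived geometry -------------------------------------------------
    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.cycle_length / self.n_frames

    @property
    def axis_xy(self) -> tuple[float, float]:
        """World (x, y) of the LV long axis (grid centre)."""
        nx, ny, _ = self.grid_shape
        return ((nx - 1) / 2.0 * self.voxel_size, (ny - 1) / 2.0 * self.voxel_size)

    @property
    def apex_z(self) -> float:
        return self.annulus_z0 + self.lv_length

    def annulus_z(self, t_ms) -> np.ndarray:
        """Annulus-plane z position: sinusoidal apical excursion."""
        s = 0.5 * (1 - np.cos(2 * np.pi * np.asarray(t_ms, float) / self.cycle_length))
        return self.annulus_z0 + self.annulus_excursion * s

    def annulus_speed_cm_s(self, t_ms) -> np.ndarray:
        """Signed annulus-plane speed along +z (toward apex), cm/s."""
        t = np.asarray(t_ms, float)
        dzdt = (
            self.annulus_excursion
            * (np.pi / self.cycle_length)
            * np.sin(2 * np.pi * t / self.cycle_length)
        )  # mm/ms
        return 100.0 * dzdt

    @property
    def axial_attenuation_at_plane(self) -> float:
        """Jet axial factor at the annulus plane relative to the vena contracta."""
        d = self.vena_contracta_offset
        return float(np.exp(-(d**2) / (2 * self.axial_sigma_down**2)))


def _raised_cosine(t, center: float, half_width: float, amplitude: float) -> np.ndarray:
    x = np.asarray(t, dtype=float) - center
    out = np.zeros_like(x, dtype=float)
    m = np.abs(x) < half_width
    out[m] = amplitude * np.cos(np.pi * x[m] / (2 * half_width)) ** 2
    return out


def inflow_envelope(t_ms, params: PhantomParams) -> np.ndarray:
    """Transmitral inflow envelope (cm/s) at the vena contracta: E + A pulses."""
    t_e = params.e_peak_time_frac * params.cycle_length
    t_a = params.a_peak_time_frac * params.cycle_length
    return _raised_cosine(t_ms, t_e, params.e_width, params.peak_e_velocity) + _raised_cosine(
        t_ms, t_a, params.a_width, params.peak_a_velocity
    )


def _systolic_envelope(t_ms, params: PhantomParams) -> np.ndarray:
    return _raised_cosine(
        t_ms,
        params.systolic_peak_time_frac * params.cycle_length,
        params.systolic_width,
        params.systolic_peak_velocity,
    )


def effective_jet_area_mm2(params: PhantomParams) -> float:
    """Closed-form integral of the radial jet profile (plug core + Gaussian
    shoulder truncated at 3 sigma), in mm^2."""
    rc = params.jet_core_radius
    s = params.jet_radius
    gauss_line = s * math.sqrt(math.pi / 2) * erf(3 / math.sqrt(2))
    gauss_moment = s**2 * (1 - math.exp(-4.5))
    return math.pi * rc**2 + 2 * math.pi * (rc * gauss_line + gauss_moment)


def _radial_profile(r: np.ndarray, core: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(r)
    inside = r <= core
    out[inside] = 1.0
    shoulder = (r > core) & (r <= core + 3 * sigma)
    out[shoulder] = np.exp(-((r[shoulder] - core) ** 2) / (2 * sigma**2))
    return out


def _axial_profile(dz: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Jet axial factor vs signed distance from the vena contracta (+ = apical)."""
    out = np.zeros_like(dz)
    up = dz >= 0
    core, s_up = params.axial_core_up, params.axial_sigma_up
    flat = up & (dz <= core)
    out[flat] = 1.0
    shoulder = up & (dz > core) & (dz <= core + 3 * s_up)
    out[shoulder] = np.exp(-((dz[shoulder] - core) ** 2) / (2 * s_up**2))
    s_dn = params.axial_sigma_down
    down = (~up) & (dz >= -3 * s_dn)
    out[down] = np.exp(-(dz[down] ** 2) / (2 * s_dn**2))
    return out


def _attachment_profile(dz_ann: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Annulus-attached flow component: full at the plane, zero at the vena
    contracta and beyond (compact raised-cosine support)."""
    d = params.vena_contracta_offset
    if d <= 0:
        return np.zeros_like(dz_ann)
    out = np.zeros_like(dz_ann)
    m = np.abs(dz_ann) < d
    out[m] = np.cos(np.pi * dz_ann[m] / (2 * d)) ** 2
    return out


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    true_peak_e: float  # cm/s at the vena contracta
    true_peak_a: float
    true_ea_ratio: float
    true_peak_flow_e: float  # mL/s through the annulus plane
    true_peak_flow_a: float
    annulus_trajectory: np.ndarray  # (nt, 2, 3) landmark world coords, mm
    lv_mask: np.ndarray  # (nt, nx, ny, nz) bool
    fused: bool
    envelope_at_frames: np.ndarray  # cm/s, sampled inflow envelope
    plane_speed_at_frames: np.ndarray  # cm/s, annulus-plane normal speed
    axial_attenuation_at_plane: float

    def __post_init__(self) -> None:
        if self.true_peak_a > 0 and not np.isclose(
            self.true_ea_ratio, self.true_peak_e / self.true_peak_a
        ):
            raise ValueError("true_ea_ratio must equal true_peak_e / true_peak_a")
        empty = ~np.asarray(self.lv_mask, bool).any(axis=(1, 2, 3))
        if empty.any():
            raise ValueError("LV mask empty on some frames")


@dataclass
class Phantom:
    """Bundle returned by :func:`generate_phantom`."""

    params: PhantomParams
    velocity: VelocityField
    cine: CineSeries
    lv_mask: LVMaskSeries
    init_landmarks: dict  # {"frame_index": int, "points_mm": [[x,y,z], [x,y,z]]}
    truth: PhantomTruth


def _envelope_is_fused(params: PhantomParams) -> bool:
    """True when the summed E+A envelope has a single diastolic local maximum."""
    t = np.linspace(0, params.cycle_length, 4000, endpoint=False)
    env = inflow_envelope(t, params)
    pos = env > 1e-9
    if not pos.any():
        return True
    interior = (env[1:-1] > env[:-2]) & (env[1:-1] >= env[2:]) & pos[1:-1]
    # collapse adjacent flagged samples (flat-top numerical plateaus)
    idx = np.flatnonzero(interior)
    n_peaks = 0 if len(idx) == 0 else 1 + int(np.sum(np.diff(idx) > 1))
    return n_peaks < 2


def generate_phantom(params: Optional[PhantomParams] = None, **overrides) -> Phantom:
    """Generate a bit-reproducible synthetic 4D-flow dataset.

    Parameters may be given as a :class:`PhantomParams` or as keyword
    overrides of the defaults.  Returns the velocity field, the long-axis
    cine with annulus-landmark seeds, the ground-truth LV mask series and
    the :class:`PhantomTruth`.
    """
    if params is None:
        params = PhantomParams(**overrides)
    elif overrides:
        params = PhantomParams(**{**asdict(params), **overrides})
    p = params
    rng = np.random.default_rng(p.seed)
    nx, ny, nz = p.grid_shape
    nt = p.n_frames
    times = p.frame_times

    affine = np.diag([p.voxel_size, p.voxel_size, p.voxel_size, 1.0])
    x = np.arange(nx) * p.voxel_size
    y = np.arange(ny) * p.voxel_size
    z = np.arange(nz) * p.voxel_size
    x0, y0 = p.axis_xy
    xx, yy = np.meshgrid(x - x0, y - y0, indexing="ij")
    r_axis = np.hypot(xx, yy)  # (nx, ny), distance from LV axis
    r_out = np.hypot(xx - p.systolic_offset, yy)
    radial = _radial_profile(r_axis, p.jet_core_radius, p.jet_radius)
    radial_out = _radial_profile(r_out, 3.0, 5.0)
    # radial taper of the annulus-attached component: uniform inside the LV
    taper = np.ones_like(r_axis)
    outside = r_axis > p.lv_radius
    taper[outside] = np.exp(-((r_axis[outside] - p.lv_radius) ** 2) / (2 * 5.0**2))

    env = inflow_envelope(times, p)
    sys_env = _systolic_envelope(times, p)
    z_ann = p.annulus_z(times)
    plane_speed = p.annulus_speed_cm_s(times)

    vz = np.zeros((nx, ny, nz, nt), dtype=np.float32)
    lv_mask = np.zeros((nt, nx, ny, nz), dtype=bool)
    for t in range(nt):
        dz_vc = z[None, None, :] - (z_ann[t] + p.vena_contracta_offset)
        axial = _axial_profile(dz_vc, p)
        dz_ann = z[None, None, :] - z_ann[t]
        attach = _attachment_profile(dz_ann, p)
        frame = (
            env[t] * radial[:, :, None] * axial
            + plane_speed[t] * taper[:, :, None] * attach
        )
        if sys_env[t] > 0:
            ax_out = np.exp(-((z[None, None, :] - (z_ann[t] + 10.0)) ** 2) / (2 * 12.0**2))
            frame = frame - sys_env[t] * radial_out[:, :, None] * ax_out
        vz[..., t] = frame.astype(np.float32)
        lv_mask[t] = (r_axis[:, :, None] <= p.lv_radius) & (
            (z[None, None, :] >= z_ann[t]) & (z[None, None, :] <= p.apex_z)
        )

    data = np.zeros((3, nx, ny, nz, nt), dtype=np.float32)
    data[2] = vz
    if p.noise_sd > 0:
        data += rng.normal(0.0, p.noise_sd, size=data.shape).astype(np.float32)
    if p.inject_aliasing:
        data = ((data + p.venc) % (2 * p.venc) - p.venc).astype(np.float32)

    field = VelocityField(data=data, affine=affine, frame_times=times, venc=p.venc)

    # --- cine: long-axis plane y = y0, axes (x, z), 1 mm pixels -----------
    du = dv = p.cine_pixel_spacing
    ni = int(round(x[-1] / du)) + 1
    nj = int(round(z[-1] / dv)) + 1
    u = np.arange(ni) * du
    v = np.arange(nj) * dv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    background = 30.0 + 15.0 * np.exp(
        -((uu - x0) ** 2 + (vv - (p.annulus_z0 + 40.0)) ** 2) / (2 * 40.0**2)
    )
    blob_sigma = 2.5  # px-scale blob, in mm
    lm_x = np.array([x0 - p.annulus_radius, x0 + p.annulus_radius])
    images = np.empty((nt, ni, nj), dtype=np.float32)
    for t in range(nt):
        frame = background.copy()
        for lx in lm_x:
            frame += 200.0 * np.exp(
                -((uu - lx) ** 2 + (vv - z_ann[t]) ** 2) / (2 * blob_sigma**2)
            )
        images[t] = frame
    if p.cine_noise_sd > 0:
        images += rng.normal(0.0, p.cine_noise_sd, size=images.shape).astype(np.float32)
    cine = CineSeries(
        images=images,
        origin=np.array([0.0, y0, 0.0]),
        axis_u=np.array([1.0, 0.0, 0.0]),
        axis_v=np.array([0.0, 0.0, 1.0]),
        pixel_spacing=(du, dv),
        frame_times=times,
    )

    trajectory = np.zeros((nt, 2, 3))
    trajectory[:, 0] = np.column_stack([np.full(nt, lm_x[0]), np.full(nt, y0), z_ann])
    trajectory[:, 1] = np.column_stack([np.full(nt, lm_x[1]), np.full(nt, y0), z_ann])

    alpha = p.axial_attenuation_at_plane
    area = effective_jet_area_mm2(p)
    truth = PhantomTruth(
        true_peak_e=p.peak_e_velocity,
        true_peak_a=p.peak_a_velocity,
        true_ea_ratio=(
            p.peak_e_velocity / p.peak_a_velocity if p.peak_a_velocity > 0 else np.nan
        ),
        true_peak_flow_e=p.peak_e_velocity * alpha * area / 100.0,
        true_peak_flow_a=p.peak_a_velocity * alpha * area / 100.0,
        annulus_trajectory=trajectory,
        lv_mask=lv_mask,
        fused=_envelope_is_fused(p),
        envelope_at_frames=env,
        plane_speed_at_frames=plane_speed,
        axial_attenuation_at_plane=alpha,
    )

    init_landmarks = {
        "frame_index": 0,
        "points_mm": trajectory[0].tolist(),
    }
    return Phantom(
        params=p,
        velocity=field,
        cine=cine,
        lv_mask=LVMaskSeries(masks=lv_mask, provenance="phantom_truth"),
        init_landmarks=init_landmarks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Synthetic paired measurement tables for the agreement-statistics stage
# ---------------------------------------------------------------------------

@dataclass
class MethodModel:
    """Linear measurement model of one method against the echo reference:
    ``y = slope * x + intercept + N(0, noise_sd)``, applied per metric."""

    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Default method models per metric, emulating the association strengths
#: observed between 4D-flow methods and echo in an ischemic-heart-disease
#: cohort (slopes/intercepts from the reported regressions; noise SDs chosen
#: to reproduce the corresponding R^2 given the echo spread simulated here).
DEFAULT_METHOD_MODELS: dict[str, dict[str, MethodModel]] = {
    "lvvel": {
        "ea": MethodModel(0.86, 0.16, 0.24),
        "peak_e": MethodModel(0.49, 29.0, 10.2),
        "peak_a": MethodModel(0.47, 29.0, 7.1),
    },
    "mvvel": {
        "ea": MethodModel(0.78, 0.21, 0.29),
        "peak_e": MethodModel(0.11, 39.0, 9.7),
        "peak_a": MethodModel(0.23, 31.0, 6.6),
    },
    "mvflow": {
        "ea": MethodModel(0.89, 0.16, 0.34),
        "peak_e": MethodModel(0.45, 30.0, 10.5),
        "peak_a": MethodModel(0.44, 30.0, 7.5),
    },
}

METRICS = ("ea", "peak_e", "peak_a")


def make_paired_measurements(
    n_subjects: int = 77,
    echo_ea_mean: float = 1.0,
    echo_ea_sd: float = 0.5,
    method_models: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-subject measurement table with known method/echo relations.

    Echo E/A ratios are drawn log-normally (clipped to 0.4-2.8, matching an
    elderly ischemic cohort), peak A in cm/s, and peak E = ratio * peak A.
    Each method's value for each metric follows its linear
    :class:`MethodModel` against the echo value.  Returns a tidy table with
    columns ``subject_id, metric, method, value``.

    ``method_models`` maps method name to either a single MethodModel
    (applied to every metric) or a dict metric -> MethodModel.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if echo_ea_sd <= 0:
        raise ValueError("echo_ea_sd must be positive")
    if method_models is None:
        method_models = DEFAULT_METHOD_MODELS
    rng = np.random.default_rng(seed)

    # lognormal with the requested mean/sd
    var = echo_ea_sd**2
    mu = math.log(echo_ea_mean**2 / math.sqrt(var + echo_ea_mean**2))
    sig = math.sqrt(math.log(1 + var / echo_ea_mean**2))
    ea = np.clip(rng.lognormal(mu, sig, size=n_subjects), 0.4, 2.8)
    peak_a = np.clip(rng.normal(65.0, 12.0, size=n_subjects), 30.0, None)
    peak_e = ea * peak_a
    echo = {"ea": ea, "peak_e": peak_e, "peak_a": peak_a}

    rows = []
    subjects = [f"s{i + 1:03d}" for i in range(n_subjects)]
    for metric in METRICS:
        for sid, val in zip(subjects, echo[metric]):
            rows.append((sid, metric, "echo", float(val)))
    for method, model in method_models.items():
        for metric in METRICS:
            m = model[metric] if isinstance(model, dict) else model
            if m.noise_sd < 0:
                raise ValueError("noise_sd must be non-negative")
            noise = rng.normal(0.0, m.noise_sd, size=n_subjects) if m.noise_sd > 0 else 0.0
            vals = m.slope * echo[metric] + m.intercept + noise
            for sid, val in zip(subjects, vals):
                rows.append((sid, metric, method, float(val)))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "method", "value"])
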