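"""Mitral annulus tracking on a long-axis cine series.

From a single end-diastolic initialization of the two annulus landmarks,
each landmark is followed frame-to-frame by normalized cross-correlation
(NCC) template matching, once forward and once backward around the cardiac
cycle.  The two passes are fused by weighted averaging with weights
decreasing linearly with the number of steps from the start frame, so the
combined track is exact at the initialization and degrades gracefully as
drift accumulates.  The tracked landmark chord defines the annulus plane;
the plane's own velocity along its normal is estimated by cyclic central
differences for downstream motion correction of through-plane velocities.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import match_template

from .datatypes import CineSeries, PlanePose, TrackedPlane

__all__ = [
    "TrackingError",
    "track_landmarks",
    "landmarks_to_plane",
    "plane_velocity",
]


class TrackingError(RuntimeError):
    """Raised when NCC tracking is too unreliable to continue."""


def _extract_patch(image: np.ndarray, center: tuple[int, int], half: int) -> np.ndarray:
    """Edge-replicated square patch of half-size ``half`` around ``center``."""
    ni, nj = image.shape
    ci, cj = center
    i0, i1 = ci - half, ci + half + 1
    j0, j1 = cj - half, cj + half + 1
    pad_i0, pad_j0 = max(0, -i0), max(0, -j0)
    pad_i1, pad_j1 = max(0, i1 - ni), max(0, j1 - nj)
    patch = image[max(i0, 0) : min(i1, ni), max(j0, 0) : min(j1, nj)]
    if pad_i0 or pad_i1 or pad_j0 or pad_j1:
        patch = np.pad(patch, ((pad_i0, pad_i1), (pad_j0, pad_j1)), mode="edge")
    return patch


def _subpixel_offset(corr: np.ndarray, peak: tuple[int, int]) -> np.ndarray:
    """Quadratic refinement of the NCC peak from its 3x3 neighbourhood."""
    offset = np.zeros(2)
    for ax in range(2):
        idx = peak[ax]
        if idx <= 0 or idx >= corr.shape[ax] - 1:
            continue
        sel = list(peak)
        sel[ax] = slice(idx - 1, idx + 2)
        cm, c0, cp = corr[tuple(sel)]
        denom = cm - 2 * c0 + cp
        if abs(denom) > 1e-12:
            offset[ax] = np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0)
    return offset


def _track_one_pass(
    frames: np.ndarray,
    start: np.ndarray,
    init_frame: int,
    direction: int,
    template_size: int,
    search_radius: int,
) -> tuple[np.ndarray, list[float]]:
    """Track a single landmark through one full cyclic pass.

    Returns per-frame positions (nt, 2) and the NCC peak value of every step.
    """
    nt = frames.shape[0]
    half_t = template_size // 2
    half_s = half_t + search_radius
    pos = np.zeros((nt, 2))
    pos[init_frame] = start
    peaks = []
    cur = np.asarray(start, dtype=float)
    for step in range(1, nt):
        prev_f = (init_frame + direction * (step - 1)) % nt
        f = (init_frame + direction * step) % nt
        center = tuple(np.round(cur).astype(int))
        template = _extract_patch(frames[prev_f], center, half_t)
        search = _extract_patch(frames[f], center, half_s)
        corr = match_template(search, template)  # (2*search_radius+1)^2
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        peaks.append(float(corr[peak]))
        disp = np.array(peak, dtype=float) - search_radius + _subpixel_offset(corr, peak)
        # displacement is measured between content of patches cut at the same
        # centre, so it updates the (fractional) estimate directly; re-anchoring
        # on the rounded centre would accumulate rounding residuals as drift
        cur = cur + disp
        pos[f] = cur
    return pos, peaks


def track_landmarks(
    cine: CineSeries,
    init_landmarks: np.ndarray,
    init_frame: int = 0,
    template_size: int = 21,
    search_radius: int = 10,
    ncc_floor: float = 0.3,
    max_bad_fraction: float = 0.25,
) -> np.ndarray:
    """Track two annulus landmarks over the cardiac cycle.

    Parameters
    ----------
    init_landmarks : array (2, 2)
        Pixel coordinates (u, v) of the two landmarks at ``init_frame``.
    template_size, search_radius : int
        NCC template edge (pixels, odd) and search half-window (pixels).
    ncc_floor, max_bad_fraction : float
        A pass step whose NCC peak falls below ``ncc_floor`` counts as bad;
        if more than ``max_bad_fraction`` of all steps are bad a
        :class:`TrackingError` is raised.

    Returns
    -------
    tracks : ndarray (2, n_frames, 2)
        Per-frame pixel positions of each landmark, combined from the
        forward and backward passes with linearly decreasing weights
        w_f = (T - t)/T and w_b = t/T after t forward steps of T.
    """
    init = np.asarray(init_landmarks, dtype=float)
    if init.shape != (2, 2):
        raise ValueError("init_landmarks must be two (u, v) pixel points")
    nt, ni, nj = cine.images.shape
    if not 0 <= init_frame < nt:
        raise ValueError("init_frame out of range")
    if np.any(init < 0) or np.any(init[:, 0] > ni - 1) or np.any(init[:, 1] > nj - 1):
        raise ValueError("initial landmarks must lie inside the image")
    if template_size % 2 == 0 or template_size < 3:
        raise ValueError("template_size must be odd and >= 3")

    frames = cine.images.astype(float)
    steps = (np.arange(nt) - init_frame) % nt  # forward steps to reach each frame
    w_f = (nt - steps) / nt
    w_b = steps / nt

    tracks = np.zeros((2, nt, 2))
    all_peaks: list[float] = []
    for lm in range(2):
        fwd, pk_f = _track_one_pass(
            frames, init[lm], init_frame, +1, template_size, search_radius
        )
        bwd, pk_b = _track_one_pass(
            frames, init[lm], init_frame, -1, template_size, search_radius
        )
        all_peaks.extend(pk_f)
        all_peaks.extend(pk_b)
        tracks[lm] = w_f[:, None] * fwd + w_b[:, None] * bwd
        tracks[lm, init_frame] = init[lm]

    bad = np.mean(np.asarray(all_peaks) < ncc_floor) if all_peaks else 0.0
    if bad > max_bad_fraction:
        raise TrackingError(
            f"NCC peak below {ncc_floor} in {bad:.0%} of tracking steps"
        )
    return tracks


def landmarks_to_plane(
    landmark_tracks: np.ndarray,
    cine: CineSeries,
    apex_hint: np.ndarray,
) -> TrackedPlane:
    """Build the annulus plane per frame from the tracked landmark chord.

    Per frame the plane origin is the chord midpoint (world mm); the plane
    contains the chord and the cine through-plane direction, and its normal
    is the in-cine-plane unit vector perpendicular to the chord, oriented
    toward ``apex_hint``.
    """
    tracks = np.asarray(landmark_tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[0] != 2 or tracks.shape[2] != 2:
        raise ValueError("landmark_tracks must be (2, n_frames, 2) pixel coords")
    nt = tracks.shape[1]
    if nt != cine.n_frames:
        raise ValueError("track length must match the cine frame count")
    apex = np.asarray(apex_hint, dtype=float)

    through = cine.through_plane
    world = np.stack(
        [cine.pixel_to_world(tracks[0]), cine.pixel_to_world(tracks[1])], axis=0
    )  # (2, nt, 3)
    poses = []
    for t in range(nt):
        p1, p2 = world[0, t], world[1, t]
        chord = p2 - p1
        norm = np.linalg.norm(chord)
        if norm < 1e-9:
            raise ValueError(f"coincident landmarks at frame {t}")
        u = chord / norm
        mid = 0.5 * (p1 + p2)
        n = np.cross(through, u)
        n /= np.linalg.norm(n)
        if np.dot(n, apex - mid) < 0:
            n = -n
        if abs(np.dot(n, apex - mid)) < 1e-9:
            raise ValueError("apex_hint lies on the landmark chord")
        poses.append(
            PlanePose(origin=mid, normal=n, basis=np.stack([u, through]), frame_index=t)
        )

    vel = _origin_normal_velocity(
        np.array([p.origin for p in poses]),
        np.array([p.normal for p in poses]),
        cine.frame_times,
    )
    return TrackedPlane(
        poses=poses,
        landmark_tracks=world,
        plane_velocity=vel,
        frame_times=cine.frame_times,
    )


def _origin_normal_velocity(
    origins: np.ndarray, normals: np.ndarray, frame_times: np.ndarray
) -> np.ndarray:
    """Signed origin speed along the per-frame normal by cyclic central
    differences, in cm/s (origins in mm, times in ms)."""
    t = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    nt = len(t)
    period = t[-1] - t[0] + np.median(np.diff(t))
    nxt = np.roll(origins, -1, axis=0)
    prv = np.roll(origins, 1, axis=0)
    dt = np.roll(t, -1) - np.roll(t, 1)
    dt[0] += period
    dt[-1] += period
    deriv = (nxt - prv) / dt[:, None]  # mm/ms
    return 100.0 * np.sum(deriv * normals, axis=1)


def plane_velocity(tracked: TrackedPlane, frame_times=None) -> np.ndarray:
    """Per-frame signed speed (cm/s) of the plane origin along its normal.

    Uses central differences with cyclic boundary (the cardiac cycle is
    periodic).  Exact for motion linear in time away from the cycle
    wraparound.
    """
    t = tracked.frame_times if frame_times is None else np.asarray(frame_times, float)
    if tracked.n_frames < 3:
        raise ValueError("need at least 3 frames")
    return _origin_normal_velocity(tracked.origins, tracked.normals, t)
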