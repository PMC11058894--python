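"""Shared fixtures: phantoms and pipeline results reused across test modules.

Session-scoped because phantom generation and the LV median filter are the
expensive steps; every fixture is deterministic (fixed seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

import mitralflow as mf

#: reduced-anatomy phantom parameters for cheap end-to-end tests
SMALL_PHANTOM = dict(
    grid_shape=(24, 24, 36),
    annulus_z0=25.0,
    lv_length=60.0,
    lv_radius=22.0,
    annulus_radius=12.0,
    annulus_excursion=8.0,
)


def apex_hint(params: mf.PhantomParams) -> np.ndarray:
    x0, y0 = params.axis_xy
    return np.array([x0, y0, params.apex_z])


def track_phantom_plane(phantom: mf.Phantom) -> mf.TrackedPlane:
    """Run the full tracking stage of a phantom: cine -> landmark tracks -> plane."""
    cine = phantom.cine
    init_px = cine.world_to_pixel(np.asarray(phantom.init_landmarks["points_mm"]))
    tracks = mf.track_landmarks(cine, init_px, init_frame=phantom.init_landmarks["frame_index"])
    return mf.landmarks_to_plane(tracks, cine, apex_hint(phantom.params))


@pytest.fixture(scope="session")
def default_phantom() -> mf.Phantom:
    """Noise-free phantom at the default acquisition/physiology settings."""
    return mf.generate_phantom(seed=7)


@pytest.fixture(scope="session")
def static_phantom() -> mf.Phantom:
    """Noise-free phantom without annulus motion, annulus on a voxel plane."""
    return mf.generate_phantom(annulus_excursion=0.0, annulus_z0=39.2, seed=1)


@pytest.fixture(scope="session")
def tracked_plane(default_phantom) -> mf.TrackedPlane:
    return track_phantom_plane(default_phantom)


@pytest.fixture(scope="session")
def lvvel_result(default_phantom) -> mf.LVResult:
    return mf.lvvel_ea(default_phantom.velocity, default_phantom.lv_mask)


@pytest.fixture(scope="session")
def mvvel_result(default_phantom, tracked_plane) -> mf.MVResult:
    return mf.mvvel_ea(default_phantom.velocity, tracked_plane)


@pytest.fixture(scope="session")
def mvflow_result(default_phantom, tracked_plane) -> mf.MVResult:
    return mf.mvflow_ea(default_phantom.velocity, tracked_plane)
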