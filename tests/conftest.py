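import numpy as np
import pytest

import valvepc as v
from valvepc import flow_quant as fq
from valvepc import synthetic_cine as sc


@pytest.fixture(scope="session")
def cone():
    return v.ConeGeometry()


@pytest.fixture(scope="session")
def phantom_grid():
    return v.ImageGrid.from_fov(128, 250.0, 8.0)


@pytest.fixture(scope="session")
def default_scene():
    """One seeded slice-following heart scene with mild regurgitation."""
    params = v.HeartSceneParams(seed=7, regurgitant_volume_ml=10.0)
    series, traj, gt = v.simulate_heart_scene(params, plane_mode="following")
    return params, series, traj, gt


@pytest.fixture(scope="session")
def default_scene_rois(default_scene):
    params, series, _, _ = default_scene
    polys = sc.scene_roi_polygons(params, series.grid)
    return {
        "mitral": fq.RoiSeries("mitral", polys["mitral"]),
        "static": fq.RoiSeries("static-tissue", polys["static"]),
    }


def square_roi(r0, c0, r1, c1):
    """Axis-aligned rectangle polygon covering pixel centres [r0,r1]×[c0,c1]."""
    return np.array(
        [
            [r0 - 0.4, c0 - 0.4],
            [r0 - 0.4, c1 + 0.4],
            [r1 + 0.4, c1 + 0.4],
            [r1 + 0.4, c0 - 0.4],
        ]
    )


@pytest.fixture
def flat_series():
    """10-phase 20×20 series (1 mm pixels) with all-zero velocity."""
    grid = v.ImageGrid(20, 20, 1.0, 8.0, 20.0)
    n = 10
    return v.CinePCSeries(
        magnitude=np.ones((n, 20, 20)),
        velocity=np.zeros((n, 20, 20)),
        venc=150.0,
        phase_times=(np.arange(n) + 0.5) * 100.0,
        phase_durations=np.full(n, 100.0),
        grid=grid,
        slice_offsets=np.zeros(n),
    )
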