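import math

import numpy as np
import pytest

from edgedyn.config import KinematicPulse, SimConfig
from edgedyn.segmentation import CellMask, boundary_from_polyline
from edgedyn.synthetic import generate_cell_movie


def make_disk_mask(radius_um: float, pixel_size_um: float, shape=(256, 256)) -> CellMask:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2, (h - 1) / 2
    r_px = radius_um / pixel_size_um
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= r_px**2
    return CellMask(mask=mask, pixel_size_um=pixel_size_um)


def make_circle_boundary(radius_um: float, n: int = 1440, center=(40.0, 40.0),
                         pixel_size_um: float = 0.2):
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    xy = np.column_stack(
        [center[0] + radius_um * np.cos(theta), center[1] + radius_um * np.sin(theta)]
    )
    return boundary_from_polyline(xy, pixel_size_um=pixel_size_um)


@pytest.fixture(scope="session")
def pulse_movie():
    """Small two-channel movie with one protrusion pulse and rho = 0.8."""
    cfg = SimConfig(
        n_frames=12,
        image_shape=(300, 300),
        coloc_rho=0.8,
        seed=1,
        cell_radius_um=20.0,
        boundary_kinematics=[
            KinematicPulse("protrusion", 2, 9, 30.0, 24.0, 0.1)
        ],
    )
    movie, gt = generate_cell_movie(cfg)
    return cfg, movie, gt
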