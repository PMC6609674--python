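import math

import numpy as np
import pytest

from otlskit.geometry import ScanGeometry, plan_tiles
from otlskit.phantom import Phantom, make_phantom, render_dataset
from otlskit.reconstruct import deskew, shear_shift_per_row


@pytest.fixture(scope="session")
def toy_scan() -> ScanGeometry:
    """Coarse-sampling scan geometry with an exactly matched frame interval."""
    return ScanGeometry.from_sampling(0.8, 45.0, 800.0)


@pytest.fixture(scope="session")
def toy_dataset(toy_scan):
    """A small noiseless 3 x 2-tile two-channel simulated dataset.

    Returns (phantom, plan, scan, strips, records, rows, cols).
    """
    rows, cols = 24, 48
    samp = toy_scan.sampling_um
    fov_h = cols * samp
    strip_h = rows * samp * math.cos(math.radians(toy_scan.tilt_deg))
    shift = shear_shift_per_row(toy_scan)
    plan = plan_tiles((30.0, 80.0, 18.0), fov_h, strip_h,
                      lateral_pitch_um=25.6, vertical_pitch_um=6.3,
                      frame_interval_um=toy_scan.frame_interval_um,
                      lead_in_frames=(rows - 1) * shift)
    phantom = make_phantom((30.0, 80.0, 18.0), n_nuclei=25, n_filaments=5,
                           seed=3, voxel_pitch_um=0.5,
                           nucleus_radius_um=(1.5, 2.5))
    strips, records = render_dataset(phantom, plan, toy_scan, rows, cols,
                                     sheet=None, seed=1)
    return phantom, plan, toy_scan, strips, records, rows, cols


def deskew_all(strips, shift, channel):
    return [deskew(s, shift) for s in strips if s.channel == channel]


@pytest.fixture(scope="session")
def uniform_phantom():
    """Spatially constant single-channel phantom for invariance tests."""
    vol = np.full((100, 40, 60), 1000.0, dtype=np.float32)
    return Phantom((49.5, 19.5, 29.5), (0.5, 0.5, 0.5), {"nuclear": vol})
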