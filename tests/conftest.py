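"""Shared fixtures: rendered speckle images and small synthetic sequences."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import cardiodic as cd
from cardiodic.dic import SubsetGrid


@pytest.fixture(scope="session")
def speckle_image():
    """Clean 256x256 speckle pattern (no sensor noise), float."""
    params = cd.SpecklePatternParams(seed=42, noise_sigma=0.0)
    return cd.render_speckle_pattern(params, 256, 256, 0.1).astype(float)


@pytest.fixture(scope="session")
def test_grid(speckle_image):
    """Subset-31 / step-10 lattice with >= 100 points, central ROI."""
    h, w = speckle_image.shape
    grid = SubsetGrid.from_roi((60, 60, 136, 136), (h, w), subset_size=31, step=10)
    assert grid.n_points >= 100
    return grid


def shift_image(image, dx, dy):
    """Shift image content by (+dx, +dy) px via bicubic resampling."""
    return ndi.shift(image, (dy, dx), order=3, mode="mirror")


def roll_image(image, dx, dy):
    """Lossless integer shift of image content by (+dx, +dy) px."""
    return np.roll(image, (dy, dx), axis=(0, 1))


@pytest.fixture(scope="session")
def beat_sequence_2d():
    """Small single-camera beating sequence with analytic ground truth.

    256x256 at 0.1 mm/px, 15 Hz, three ~0.8 s beats, mild translation and
    20% contraction, shallow respiratory modulation, 8-bit sensor noise.
    """
    pattern = cd.SpecklePatternParams(seed=7)
    motion = cd.MotionModelParams(
        heart_rate=75.0, contraction_amplitude=0.2, anisotropy=(1.0, 0.8),
        translation_amplitude=(1.2, -0.8, 0.0), respiration_mod_depth=0.03,
        respiration_rate=12.0, n_beats=4, seed=7,
    )
    grid = SubsetGrid.from_roi((64, 64, 128, 128), (256, 256),
                               subset_size=31, step=16)
    ext_px = np.array([[76.0, 128.0], [176.0, 128.0]])
    seq, gt = cd.generate_sequence(
        pattern, motion, image_size=(256, 256), mm_per_px=0.1,
        frame_rate=15.0, n_frames=52, grid=grid, extensometer_px=ext_px,
    )
    return {"seq": seq, "gt": gt, "grid": grid, "ext_px": ext_px,
            "pattern": pattern, "motion": motion, "mm_per_px": 0.1}


@pytest.fixture(scope="session")
def tracked_beat_2d(beat_sequence_2d):
    field = cd.accumulate_sequence(beat_sequence_2d["seq"], beat_sequence_2d["grid"],
                                   mm_per_px=beat_sequence_2d["mm_per_px"])
    return field
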