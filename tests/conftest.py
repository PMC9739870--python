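import numpy as np
import pytest

from salamorph.formats import flip_y
from salamorph.morphometrics import (
    ConsensusFrame,
    LandmarkConfiguration,
    build_mask,
    build_pixel_matrix,
    gpa_consensus,
    warp_to_consensus,
)
from salamorph.synthetic import SyntheticDesign, generate_head_dataset


def head_pixel_matrix(seed: int, grid=(128, 128), frame_rc=(96, 72), design_kwargs=None):
    """Run the geometric pipeline on one synthetic head dataset."""
    design = SyntheticDesign(seed=seed, **(design_kwargs or {}))
    records, rasters, labels = generate_head_dataset(design, grid=grid)
    configs = [
        LandmarkConfiguration(points=flip_y(r.points, grid[0]), id=r.id) for r in records
    ]
    consensus = gpa_consensus(configs)
    frame = ConsensusFrame.fit(consensus.mean, *frame_rc)
    mask = build_mask(frame)
    warped = [warp_to_consensus(img, c, frame) for img, c in zip(rasters, configs)]
    pm = build_pixel_matrix(warped, mask, frame, ids=[c.id for c in configs])
    return pm, labels, frame, consensus


@pytest.fixture(scope="session")
def default_head():
    """Default-design head dataset run through GPA/warping (seed 0)."""
    return head_pixel_matrix(seed=0)


@pytest.fixture(scope="session")
def separable_pixels():
    """Two perfectly separated binary patterns: all-zeros vs all-ones rows."""
    Y = np.vstack([np.zeros((10, 10)), np.ones((10, 10))]).astype(np.uint8)
    truth = np.repeat([0, 1], 10)
    return Y, truth


@pytest.fixture(scope="session")
def biometric_df():
    from salamorph.synthetic import generate_biometric_dataset

    return generate_biometric_dataset(SyntheticDesign(seed=0))
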