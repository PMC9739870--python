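"""Shared helper for the example scripts: run the geometric pipeline once."""

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


def default_pixel_matrix(seed=0, grid=(128, 128), frame_rc=(96, 72)):
    records, rasters, labels = generate_head_dataset(SyntheticDesign(seed=seed), grid=grid)
    configs = [LandmarkConfiguration(points=flip_y(r.points, grid[0]), id=r.id) for r in records]
    consensus = gpa_consensus(configs)
    frame = ConsensusFrame.fit(consensus.mean, *frame_rc)
    mask = build_mask(frame)
    warped = [warp_to_consensus(img, c, frame) for img, c in zip(rasters, configs)]
    return build_pixel_matrix(warped, mask, frame, ids=[c.id for c in configs]), labels
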