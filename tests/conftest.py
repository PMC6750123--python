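"""Shared fixtures: small, fast phantoms and helpers for transform accuracy."""

from __future__ import annotations

import numpy as np
import pytest

import medbridge as mb

# desk-scale test grid: same physical extent as the default phantom at a
# coarser resolution, so geometry stays comparable while tests run fast
SMALL_SHAPE = (64, 64, 64)
SMALL_VOX = (3.0, 3.0, 3.0)


def small_spec(**overrides) -> mb.PhantomSpec:
    kwargs = dict(grid_shape=SMALL_SHAPE, voxel_size=SMALL_VOX)
    kwargs.update(overrides)
    return mb.PhantomSpec(**kwargs)


def noiseless_spec(**overrides) -> mb.PhantomSpec:
    return small_spec(noise_sigma=0.0, bias_field_amplitude=0.0, neck_extent=0.0,
                      fov_pad_mm=0.0, **overrides)


@pytest.fixture(scope="session")
def canonical_small():
    return mb.make_canonical_brain(3, noiseless_spec())


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 mediators, 2 subjects on the small grid, full realism defaults."""
    return mb.make_cohort(3, 2, seed=5, spec=small_spec())


def mean_displacement_mm(recovered: mb.AffineTransform, truth: np.ndarray,
                         mask: mb.BinaryMask, volume: mb.Volume) -> float:
    """Mean world-space displacement between two pull-backs over mask voxels."""
    idx = np.argwhere(mask.data > 0)[::7].T.astype(float)
    pts = volume.world_coords(idx)
    pts_h = np.vstack([pts, np.ones((1, pts.shape[1]))])
    delta = (recovered.matrix @ pts_h - truth @ pts_h)[:3]
    return float(np.linalg.norm(delta, axis=0).mean())


def random_volume(rng: np.random.Generator, shape=(8, 8, 8), lo=0.0, hi=100.0) -> mb.Volume:
    return mb.Volume(rng.uniform(lo, hi, size=shape).astype(np.float32), np.eye(4))


def random_mask(rng: np.random.Generator, shape=(8, 8, 8), p=0.4) -> mb.BinaryMask:
    return mb.BinaryMask((rng.random(shape) < p).astype(np.uint8), np.eye(4))
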