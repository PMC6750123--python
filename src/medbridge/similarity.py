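"""Image-similarity criteria and mask-overlap evaluation.

Three criteria drive the mediator framework: SSD (sum of squared intensity
differences, computed after histogram matching because it is sensitive to
the intensity mapping), mutual information (intensity-mapping-free, from a
joint histogram, in bits), and the Dice overlap of binary brain masks used
to *evaluate* registrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import BinaryMask, Volume

__all__ = [
    "SimilarityScore",
    "histogram_match",
    "ssd",
    "mutual_information",
    "dice",
]

DEFAULT_MI_BINS = 64
DEFAULT_MATCH_LEVELS = 256


@dataclass
class SimilarityScore:
    criterion: str  # "ssd" | "mi" | "dice"
    value: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.criterion not in ("ssd", "mi", "dice"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.criterion in ("ssd", "mi") and self.value < 0:
            raise ValueError(f"{self.criterion} must be non-negative")
        if self.criterion == "dice" and not (0 <= self.value <= 1):
            raise ValueError("dice must lie in [0,1]")


def _same_grid(a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def histogram_match(source: Volume, reference: Volume, n_levels: int = DEFAULT_MATCH_LEVELS) -> Volume:
    """Monotonically remap ``source`` so its quantiles match ``reference``'s.

    Uses an ``n_levels``-point empirical CDF: source quantiles are mapped
    onto reference quantiles with linear interpolation in between.  The
    output is a monotone transform of the input.
    """
    src = source.data.astype(np.float64)
    ref = reference.data.astype(np.float64)
    if src.max() == src.min() or ref.max() == ref.min():
        raise ValueError("histogram matching needs non-constant images")
    qs = np.linspace(0.0, 1.0, int(n_levels))
    src_q = np.quantile(src, qs)
    ref_q = np.quantile(ref, qs)
    matched = np.interp(src.reshape(-1), src_q, ref_q).reshape(src.shape)
    return Volume(matched.astype(np.float32), source.voxel_to_world.copy())


def ssd(x: Volume, y: Volume) -> float:
    """Sum over the whole grid of squared intensity differences; >= 0."""
    _same_grid(x, y)
    diff = x.data.astype(np.float64) - y.data.astype(np.float64)
    return float(np.sum(diff * diff))


def mutual_information(x: Volume, y: Volume, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Mutual information in bits from an ``n_bins`` x ``n_bins`` joint histogram.

    Bins are equal-width over each image's [min, max]; zero-count cells
    contribute nothing.  MI(X, X) equals the marginal entropy H(X) of the
    binned image.  Raw (unnormalised) MI, so the value is not bounded by 1.
    """
    _same_grid(x, y)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xf = x.data.reshape(-1).astype(np.float64)
    yf = y.data.reshape(-1).astype(np.float64)
    joint, _, _ = np.histogram2d(xf, yf, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))
    return max(mi, 0.0)


def dice(x: BinaryMask, y: BinaryMask) -> float:
    """Dice overlap 2|X n Y| / (|X| + |Y|) by voxel counting, in [0, 1]."""
    _same_grid(x, y)
    nx = int(x.data.sum())
    ny = int(y.data.sum())
    if nx + ny == 0:
        raise ValueError("both masks are empty")
    inter = int(np.sum((x.data > 0) & (y.data > 0)))
    return 2.0 * inter / (nx + ny)
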