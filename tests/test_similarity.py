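"""Similarity criteria against independent brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medbridge as mb
from medbridge.similarity import dice, histogram_match, mutual_information, ssd

from .conftest import random_mask, random_volume


def ssd_loop_oracle(x, y):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for k in range(x.shape[2]):
                d = float(x[i, j, k]) - float(y[i, j, k])
                total += d * d
    return total


def mi_histogram_oracle(x, y, n_bins):
    """Joint-histogram MI in bits, binned independently of np.histogram2d."""
    def bin_of(vals):
        lo, hi = float(vals.min()), float(vals.max())
        width = (hi - lo) / n_bins if hi > lo else 1.0
        idx = np.minimum(((vals - lo) / width).astype(int), n_bins - 1)
        return idx

    bx = bin_of(x.reshape(-1).astype(np.float64))
    by = bin_of(y.reshape(-1).astype(np.float64))
    joint = np.zeros((n_bins, n_bins))
    for a, b in zip(bx, by):
        joint[a, b] += 1
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mi = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            if pxy[a, b] > 0:
                mi += pxy[a, b] * np.log2(pxy[a, b] / (px[a] * py[b]))
    return mi


def dice_loop_oracle(x, y):
    inter = nx = ny = 0
    for xv, yv in zip(x.reshape(-1), y.reshape(-1)):
        nx += xv > 0
        ny += yv > 0
        inter += (xv > 0) and (yv > 0)
    return 2 * inter / (nx + ny)


class TestSSD:
    def test_zero_for_identical(self):
        rng = np.random.default_rng(0)
        v = random_volume(rng)
        assert ssd(v, v) == 0.0

    def test_single_voxel_difference(self):
        a = mb.Volume(np.zeros((4, 4, 4)), np.eye(4))
        bdat = np.zeros((4, 4, 4))
        bdat[1, 2, 3] = 7.0
        b = mb.Volume(bdat, np.eye(4))
        assert ssd(a, b) == pytest.approx(49.0)

    def test_printed_example(self):
        x = mb.Volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), np.eye(4))
        y = mb.Volume(np.array([1.0, 1.0, 1.0]).reshape(3, 1, 1), np.eye(4))
        assert ssd(x, y) == pytest.approx(5.0)

    def test_symmetric_and_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x, y = random_volume(rng), random_volume(rng)
            ref = ssd_loop_oracle(x.data, y.data)
            assert ssd(x, y) == pytest.approx(ref, rel=1e-12)
            assert ssd(x, y) == pytest.approx(ssd(y, x), abs=0)

    def test_shape_mismatch(self):
        a = mb.Volume(np.zeros((4, 4, 4)), np.eye(4))
        b = mb.Volume(np.zeros((5, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="mismatch"):
            ssd(a, b)


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(2)
        v = random_volume(rng, shape=(16, 16, 16))
        n_bins = 16
        counts, _ = np.histogram(v.data.reshape(-1), bins=n_bins)
        p = counts / counts.sum()
        h = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(v, v, n_bins) == pytest.approx(h, abs=1e-12)

    def test_perfectly_dependent_binary_table_is_one_bit(self):
        # joint counts (50, 0, 0, 50)/100 -> MI = 1 bit
        data = np.concatenate([np.zeros(50), np.ones(50)]).reshape(4, 5, 5)
        x = mb.Volume(data, np.eye(4))
        assert mutual_information(x, x, n_bins=2) == pytest.approx(1.0, abs=1e-12)

    def test_independent_images_near_zero(self):
        rng_a = np.random.default_rng(100)
        rng_b = np.random.default_rng(200)
        x = random_volume(rng_a, shape=(32, 32, 32))
        y = random_volume(rng_b, shape=(32, 32, 32))
        mi = mutual_information(x, y, n_bins=16)
        assert 0.0 <= mi <= 0.05
        assert mi == pytest.approx(mi_histogram_oracle(x.data, y.data, 16), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = random_volume(rng), random_volume(rng)
            ref = mi_histogram_oracle(x.data, y.data, 8)
            assert mutual_information(x, y, 8) == pytest.approx(ref, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = random_volume(rng), random_volume(rng)
        assert mutual_information(x, y, 16) == pytest.approx(
            mutual_information(y, x, 16), abs=1e-12
        )

    def test_too_few_bins(self):
        rng = np.random.default_rng(5)
        v = random_volume(rng)
        with pytest.raises(ValueError, match="n_bins"):
            mutual_information(v, v, n_bins=1)


class TestDice:
    def test_identical_masks(self):
        rng = np.random.default_rng(6)
        m = random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0], b[2] = 1, 1
        assert dice(mb.BinaryMask(a, np.eye(4)), mb.BinaryMask(b, np.eye(4))) == 0.0

    def test_success_threshold_example(self):
        # |X| = |Y| = 100, |intersection| = 85 -> Dice 0.85
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        a.reshape(-1)[:100] = 1
        b.reshape(-1)[15:115] = 1
        assert dice(mb.BinaryMask(a, np.eye(4)), mb.BinaryMask(b, np.eye(4))) == pytest.approx(0.85)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_bounded_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_mask(rng), random_mask(rng)
        d = dice(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(dice(y, x), abs=0)
        assert d == pytest.approx(dice_loop_oracle(x.data, y.data), abs=1e-12)

    def test_both_empty_rejected(self):
        z = mb.BinaryMask(np.zeros((3, 3, 3), dtype=np.uint8), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)


class TestHistogramMatch:
    def test_self_match_within_bin(self):
        rng = np.random.default_rng(7)
        v = random_volume(rng, shape=(10, 10, 10))
        out = histogram_match(v, v, n_levels=256)
        binw = (v.data.max() - v.data.min()) / 255
        assert np.abs(out.data - v.data).max() <= binw + 1e-6

    def test_doubled_source_maps_back(self):
        rng = np.random.default_rng(8)
        ref = random_volume(rng, shape=(10, 10, 10))
        src = mb.Volume(2.0 * ref.data, ref.voxel_to_world)
        out = histogram_match(src, ref, n_levels=256)
        binw = (ref.data.max() - ref.data.min()) / 255
        assert np.abs(out.data - ref.data).max() <= binw + 1e-6

    def test_output_is_monotone_transform(self):
        rng = np.random.default_rng(9)
        src = random_volume(rng, shape=(8, 8, 8))
        ref = random_volume(rng, shape=(8, 8, 8), lo=50, hi=300)
        out = histogram_match(src, ref)
        order = np.argsort(src.data.reshape(-1))
        assert np.all(np.diff(out.data.reshape(-1)[order]) >= 0)

    def test_agrees_with_skimage(self):
        from skimage.exposure import match_histograms as sk_match

        rng = np.random.default_rng(10)
        src = random_volume(rng, shape=(12, 12, 12))
        ref = random_volume(rng, shape=(12, 12, 12), lo=10, hi=500)
        ours = histogram_match(src, ref, n_levels=1024).data
        theirs = sk_match(src.data.astype(np.float64), ref.data.astype(np.float64))
        assert np.abs(ours - theirs).max() <= (ref.data.max() - ref.data.min()) / 100

    def test_constant_input_rejected(self):
        const = mb.Volume(np.full((4, 4, 4), 5.0), np.eye(4))
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="non-constant"):
            histogram_match(const, random_volume(rng, shape=(4, 4, 4)))
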