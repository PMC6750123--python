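"""Similarity matrix, complete-linkage clustering, medoids, library shrinkage."""

import itertools

import numpy as np
import pytest

import medbridge as mb
from medbridge.shrinkage import (
    ClusterAssignment,
    SimilarityMatrix,
    build_similarity_matrix,
    cluster_library,
    shrink_library,
)

from .conftest import small_spec


def toy_matrix():
    # two near-duplicates (a, b), two distinct (c, d)
    ids = ["a", "b", "c", "d"]
    vals = np.array(
        [
            [0.0, 1.0, 10.0, 14.0],
            [1.0, 0.0, 11.0, 15.0],
            [10.0, 11.0, 0.0, 12.0],
            [14.0, 15.0, 12.0, 0.0],
        ]
    )
    return SimilarityMatrix(ids, vals, symmetrized=True)


def complete_linkage_height(vals, members_a, members_b):
    return max(vals[i, j] for i in members_a for j in members_b)


def exhaustive_best_partition(vals, k):
    """All k-partitions of range(n), scored by the maximal within-cluster
    diameter (what a complete-linkage dendrogram cut minimises)."""
    n = vals.shape[0]
    best, best_score = None, np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        clusters = [[i for i in range(n) if labels[i] == c] for c in set(labels)]
        score = max(
            (vals[i, j] for cl in clusters for i in cl for j in cl), default=0.0
        )
        if score < best_score:
            best_score = score
            best = frozenset(frozenset(cl) for cl in clusters)
    return best


class TestSimilarityMatrixType:
    def test_symmetrize_averages_and_zeroes_diagonal(self):
        vals = np.array([[0.5, 2.0], [4.0, 0.1]])
        sym = SimilarityMatrix(["x", "y"], vals).symmetrize()
        assert sym.values[0, 1] == pytest.approx(3.0)
        assert sym.values[1, 0] == pytest.approx(3.0)
        assert sym.values[0, 0] == 0.0

    def test_asymmetric_flagged_matrix_rejected(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            SimilarityMatrix(["x", "y"], vals, symmetrized=True)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimilarityMatrix(["x", "y"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestClusterLibrary:
    def test_k_equals_n_gives_singletons(self):
        sim = toy_matrix()
        asg = cluster_library(sim, 4)
        assert asg.k == 4
        assert set(asg.representatives.values()) == {"a", "b", "c", "d"}
        for mid, c in asg.labels.items():
            assert asg.representatives[c] == mid

    def test_k_one_groups_everything(self):
        asg = cluster_library(toy_matrix(), 1)
        assert len(set(asg.labels.values())) == 1
        # medoid: minimal summed dissimilarity (a: 25, b: 27, c: 33, d: 41)
        assert list(asg.representatives.values()) == ["a"]

    def test_near_duplicates_cluster_together_at_k3(self):
        sim = toy_matrix()
        asg = cluster_library(sim, 3)
        assert asg.labels["a"] == asg.labels["b"]
        assert len({asg.labels["a"], asg.labels["c"], asg.labels["d"]}) == 3
        got = {}
        for mid, c in asg.labels.items():
            got.setdefault(c, set()).add(mid)
        expected = exhaustive_best_partition(sim.values, 3)
        assert frozenset(frozenset({"a": 0, "b": 1, "c": 2, "d": 3}[m] for m in cl)
                         for cl in got.values()) == expected

    def test_nested_partitions_across_k(self):
        sim = toy_matrix()
        partitions = {}
        for k in (4, 3, 2, 1):
            asg = cluster_library(sim, k)
            groups = {}
            for mid, c in asg.labels.items():
                groups.setdefault(c, set()).add(mid)
            partitions[k] = list(groups.values())
        for k_fine, k_coarse in ((4, 3), (3, 2), (2, 1)):
            for fine in partitions[k_fine]:
                assert any(fine <= coarse for coarse in partitions[k_coarse])

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must"):
            cluster_library(toy_matrix(), 0)
        with pytest.raises(ValueError, match="k must"):
            cluster_library(toy_matrix(), 5)

    def test_representative_must_belong_to_cluster(self):
        with pytest.raises(ValueError, match="not a member"):
            ClusterAssignment(k=2, labels={"a": 1, "b": 2}, representatives={1: "b", 2: "a"})


class TestOnPhantomLibrary:
    @pytest.fixture(scope="class")
    def four_phantom_matrix(self):
        """4 mediators, two sharing (nearly) the same anatomy."""
        spec = small_spec(noise_sigma=1.0, bias_field_amplitude=0.02)
        lib, _ = mb.make_cohort(3, 1, seed=13, spec=spec)
        # duplicate the first mediator under a small extra pose as a 4th entry
        canon_like = lib.entries[0]
        twin_pose = np.r_[2.0, -1.5, 1.0, 3.0, -2.0, 1.0, 1.01, 0.99, 1.0, 0.0, 0.0, 0.0]
        sample = mb.PhantomSample(
            volume=canon_like.volume,
            brain_mask=canon_like.mask,
            true_to_canonical=canon_like.to_template.relabel("twin", "template"),
            id="twin",
        )
        twin = mb.perturb(sample, twin_pose, fov="same", noise_sigma=1.0, seed=99)
        entries = lib.entries + [
            mb.MediatorEntry("twin", twin.volume, twin.true_to_canonical, twin.brain_mask)
        ]
        lib4 = mb.MediatorLibrary(lib.template, lib.template_mask, entries, "template")
        return lib4, build_similarity_matrix(lib4)

    def test_matrix_is_symmetric_zero_diagonal(self, four_phantom_matrix):
        _, sim = four_phantom_matrix
        assert sim.symmetrized
        assert np.abs(sim.values - sim.values.T).max() <= 1e-9
        assert np.abs(np.diag(sim.values)).max() == 0.0

    def test_near_duplicate_pair_is_minimum(self, four_phantom_matrix):
        _, sim = four_phantom_matrix
        i, j = sim.ids.index("m00"), sim.ids.index("twin")
        off = [sim.values[a, b] for a in range(4) for b in range(a + 1, 4)]
        assert sim.values[i, j] == min(off)

    def test_k3_isolates_the_duplicate_pair_like_exhaustive_oracle(self, four_phantom_matrix):
        lib4, sim = four_phantom_matrix
        asg = cluster_library(sim, 3)
        assert asg.labels["m00"] == asg.labels["twin"]
        got = {}
        for mid, c in asg.labels.items():
            got.setdefault(c, set()).add(sim.ids.index(mid))
        assert frozenset(frozenset(cl) for cl in got.values()) == \
            exhaustive_best_partition(sim.values, 3)
        reduced = shrink_library(lib4, asg)
        assert len(reduced) == 3
        assert reduced.ids() == [r for r in lib4.ids() if r in set(asg.representatives.values())]


class TestShrinkLibrary:
    def test_k_equals_n_identity(self):
        rng = np.random.default_rng(0)
        aff = np.eye(4)
        entries = [
            mb.MediatorEntry(
                f"m{i}",
                mb.Volume(rng.uniform(0, 1, (6, 6, 6)), aff),
                mb.AffineTransform.identity(f"m{i}", "t"),
            )
            for i in range(3)
        ]
        lib = mb.MediatorLibrary(
            mb.Volume(rng.uniform(0, 1, (6, 6, 6)), aff),
            mb.BinaryMask(np.ones((6, 6, 6), dtype=np.uint8), aff),
            entries, "t",
        )
        sim = SimilarityMatrix(lib.ids(), np.array(
            [[0, 5, 9], [5, 0, 7], [9, 7, 0]], dtype=float), symmetrized=True)
        out = shrink_library(lib, cluster_library(sim, 3))
        assert out.ids() == lib.ids()
        solo = shrink_library(lib, cluster_library(sim, 1))
        assert len(solo) == 1

    def test_unknown_representative_rejected(self):
        rng = np.random.default_rng(1)
        aff = np.eye(4)
        lib = mb.MediatorLibrary(
            mb.Volume(rng.uniform(0, 1, (6, 6, 6)), aff),
            mb.BinaryMask(np.ones((6, 6, 6), dtype=np.uint8), aff),
            [mb.MediatorEntry("m0", mb.Volume(rng.uniform(0, 1, (6, 6, 6)), aff),
                              mb.AffineTransform.identity("m0", "t"))],
            "t",
        )
        asg = ClusterAssignment(k=1, labels={"zz": 1}, representatives={1: "zz"})
        with pytest.raises(KeyError):
            shrink_library(lib, asg)
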