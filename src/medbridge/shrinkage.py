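"""Mediator-library shrinkage by SSD clustering.

Pairwise cross-registration among the mediators yields an SSD dissimilarity
matrix (a mediator that registers to another with low SSD is largely
redundant).  Complete-linkage hierarchical clustering of that matrix cut at
k groups, with the medoid of each group kept as its representative, shrinks
the library with bounded accuracy loss while cutting per-subject
registration cost by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .registration import RegistrationConfig, register_affine, resample
from .similarity import histogram_match, ssd
from .volumes_io import MediatorLibrary

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "build_similarity_matrix",
    "cluster_library",
    "shrink_library",
]


@dataclass
class SimilarityMatrix:
    """N x N cross-mediator SSD dissimilarities (zero diagonal once symmetrized)."""

    ids: list[str]
    values: np.ndarray
    symmetrized: bool = False
    failed_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be N x N matching ids")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")
        if self.symmetrized:
            if np.abs(self.values - self.values.T).max() > 1e-9:
                raise ValueError("matrix flagged symmetrized but is asymmetric")
            if np.abs(np.diag(self.values)).max() > 0:
                raise ValueError("symmetrized matrix must have zero diagonal")

    def symmetrize(self) -> "SimilarityMatrix":
        sym = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(sym, 0.0)
        return SimilarityMatrix(list(self.ids), sym, True, list(self.failed_pairs))


@dataclass
class ClusterAssignment:
    """A k-way partition of mediator ids with one medoid representative each."""

    k: int
    labels: dict[str, int]
    representatives: dict[int, str]

    def __post_init__(self) -> None:
        clusters = set(self.labels.values())
        if len(clusters) != self.k:
            raise ValueError(f"expected {self.k} non-empty clusters, got {len(clusters)}")
        for c, rep in self.representatives.items():
            if self.labels.get(rep) != c:
                raise ValueError(f"representative {rep!r} not a member of cluster {c}")


def build_similarity_matrix(
    library: MediatorLibrary, cfg: RegistrationConfig | None = None
) -> SimilarityMatrix:
    """Register every ordered mediator pair and record histogram-matched SSD.

    Entry (i, j) registers mediator i to mediator j, resamples i onto j's
    grid, histogram-matches j to the resampled i, and takes the SSD.  The
    two directed values are averaged into a symmetric matrix with zero
    diagonal.  A pair whose registration hard-fails is imputed with its row
    maximum and flagged in ``failed_pairs``.
    """
    n = len(library)
    if n < 2:
        raise ValueError("need at least 2 mediators")
    ids = library.ids()
    values = np.zeros((n, n), dtype=float)
    failed: list[tuple[str, str]] = []
    for i, ei in enumerate(library.entries):
        for j, ej in enumerate(library.entries):
            if i == j:
                continue
            try:
                reg = register_affine(ei.volume, ej.volume, cfg)
                moved = resample(ei.volume, ej.volume, reg.transform)
                matched = histogram_match(ej.volume, moved)
                values[i, j] = ssd(matched, moved)
            except Exception:
                values[i, j] = np.nan
                failed.append((ids[i], ids[j]))
    # impute failures with the row maximum of the successful entries
    for i in range(n):
        row = values[i]
        if np.any(np.isnan(row)):
            fill = np.nanmax(row) if np.any(~np.isnan(row[np.arange(n) != i])) else 0.0
            row[np.isnan(row)] = fill
    return SimilarityMatrix(ids, values, False, failed).symmetrize()


def linkage_of(sim: SimilarityMatrix) -> np.ndarray:
    """Complete-linkage dendrogram of the (symmetrized) dissimilarity matrix."""
    mat = sim if sim.symmetrized else sim.symmetrize()
    condensed = squareform(mat.values, checks=False)
    return linkage(condensed, method="complete")


def cluster_library(sim: SimilarityMatrix, k: int) -> ClusterAssignment:
    """Cut the complete-linkage dendrogram into exactly k clusters.

    Each cluster is represented by its medoid — the member minimising the
    summed dissimilarity to its co-members (a singleton represents itself);
    medoid ties break toward the earliest id in matrix order.
    """
    n = len(sim.ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    mat = sim if sim.symmetrized else sim.symmetrize()
    if k == n:
        flat = np.arange(1, n + 1)
    else:
        flat = fcluster(linkage_of(mat), t=k, criterion="maxclust")
    if len(set(flat)) != k:
        raise ValueError(f"dendrogram cut produced {len(set(flat))} clusters, wanted {k}")

    labels = {mid: int(c) for mid, c in zip(mat.ids, flat)}
    representatives: dict[int, str] = {}
    for c in sorted(set(flat)):
        members = [i for i, lab in enumerate(flat) if lab == c]
        sub = mat.values[np.ix_(members, members)]
        best_local = int(np.argmin(sub.sum(axis=1)))  # argmin takes first on ties
        representatives[int(c)] = mat.ids[members[best_local]]
    return ClusterAssignment(k=k, labels=labels, representatives=representatives)


def shrink_library(library: MediatorLibrary, assignment: ClusterAssignment) -> MediatorLibrary:
    """Keep only cluster representatives, preserving original library order."""
    unknown = set(assignment.labels) - set(library.ids())
    if unknown:
        raise KeyError(f"assignment references unknown mediators: {sorted(unknown)}")
    return library.subset(list(assignment.representatives.values()))
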