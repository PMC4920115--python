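"""Clustering of a read's monomers by pairwise sequence identity.

Identity between two monomers is ``1 - D / max(|a|, |b|)`` where ``D`` is the
unit-cost edit distance from the band-doubling greedy aligner.  Clusters at a
threshold are the connected components of the graph with an edge wherever the
pairwise identity reaches the threshold (single linkage), labelled A, B, C, …
in order of first appearance along the read.  The per-read threshold scan
walks 0.98 down to 0.88 in 0.01 steps and keeps the highest threshold whose
clustering has no singleton cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tandemhor._align import edit_distance, encode

THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.98 - 0.01 * i, 2) for i in range(11))
_EPS = 1e-9


def ordinal_label(i: int) -> str:
    """0 -> A, 1 -> B, …, 25 -> Z, 26 -> AA (spreadsheet-style)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass
class ClusterAssignment:
    """Partition of one read's monomers into similarity clusters."""

    read_id: str
    threshold: float
    labels: dict[int, str]
    cluster_sizes: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def members(self, label: str) -> list[int]:
        return [i for i in sorted(self.labels) if self.labels[i] == label]

    @property
    def multi_member_labels(self) -> list[str]:
        return [lab for lab, n in self.cluster_sizes.items() if n >= 2]


@dataclass
class ThresholdSelection:
    """Outcome of the per-read threshold scan."""

    threshold: float
    assignment: ClusterAssignment
    supports_hor: bool


def pairwise_identity(a: str, b: str) -> float:
    """Edit-distance identity ``1 - D/max(|a|,|b|)``; symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    d = edit_distance(encode(a), encode(b))
    return 1.0 - d / max(len(a), len(b))


def identity_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of pairwise identities (diagonal = 1)."""
    n = len(seqs)
    mat = np.ones((n, n), dtype=float)
    enc = [encode(s) for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            ident = 1.0 - edit_distance(enc[i], enc[j]) / max(len(seqs[i]), len(seqs[j]))
            mat[i, j] = mat[j, i] = ident
    return mat


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _components(matrix: np.ndarray, threshold: float) -> list[int]:
    n = matrix.shape[0]
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] >= threshold - _EPS:
                uf.union(i, j)
    return [uf.find(i) for i in range(n)]


def _assignment_from_matrix(
    matrix: np.ndarray, threshold: float, read_id: str
) -> ClusterAssignment:
    roots = _components(matrix, threshold)
    label_of_root: dict[int, str] = {}
    labels: dict[int, str] = {}
    sizes: dict[str, int] = {}
    for i, r in enumerate(roots):
        if r not in label_of_root:
            label_of_root[r] = ordinal_label(len(label_of_root))
        lab = label_of_root[r]
        labels[i] = lab
        sizes[lab] = sizes.get(lab, 0) + 1
    return ClusterAssignment(
        read_id=read_id, threshold=threshold, labels=labels, cluster_sizes=sizes
    )


def cluster_at_threshold(
    monomer_seqs: Sequence[str], threshold: float, read_id: str = ""
) -> ClusterAssignment:
    """Cluster monomers (already strand-normalized) at one identity threshold."""
    if not monomer_seqs:
        raise ValueError("cluster_at_threshold requires at least one monomer")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return _assignment_from_matrix(identity_matrix(monomer_seqs), threshold, read_id)


def select_threshold(
    monomer_seqs: Sequence[str],
    read_id: str = "",
    matrix: np.ndarray | None = None,
    grid: Sequence[float] = THRESHOLD_GRID,
) -> ThresholdSelection:
    """Scan the threshold grid high-to-low; keep the first HOR-supporting point.

    A clustering "supports HOR inference" when every cluster has at least two
    members.  If no grid point qualifies, the lowest-threshold assignment is
    returned with ``supports_hor=False``.
    """
    if len(monomer_seqs) < 2:
        raise ValueError("select_threshold requires at least 2 monomers")
    if matrix is None:
        matrix = identity_matrix(monomer_seqs)
    assignment = None
    for t in grid:
        assignment = _assignment_from_matrix(matrix, t, read_id)
        if min(assignment.cluster_sizes.values()) >= 2:
            return ThresholdSelection(threshold=t, assignment=assignment, supports_hor=True)
    assert assignment is not None
    return ThresholdSelection(
        threshold=grid[-1], assignment=assignment, supports_hor=False
    )
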