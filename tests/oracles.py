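"""Independent oracles used by the test suite.

These deliberately avoid the package's own alignment/clustering code paths:
edit distance comes from a full O(nm) dynamic program (pure Python for small
inputs, Biopython's C global aligner for bulk checks), and clustering from
connected components over the oracle identity graph via networkx.
"""

from __future__ import annotations

import networkx as nx
from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook full-matrix Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def fast_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance via Biopython's global aligner (unit costs)."""
    return int(-_aligner.score(a, b))


def oracle_identity(a: str, b: str) -> float:
    return 1.0 - fast_edit_distance(a, b) / max(len(a), len(b))


def oracle_clusters(seqs: list[str], threshold: float) -> list[set[int]]:
    """Connected components of the >=threshold identity graph (networkx)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if oracle_identity(seqs[i], seqs[j]) >= threshold - 1e-9:
                g.add_edge(i, j)
    return sorted(nx.connected_components(g), key=min)


def oracle_select_threshold(seqs: list[str], grid) -> tuple[float, list[set[int]]]:
    """Exhaustively evaluate every grid point; highest with all clusters >= 2."""
    last = None
    for t in grid:
        comps = oracle_clusters(seqs, t)
        last = (t, comps)
        if all(len(c) >= 2 for c in comps):
            return t, comps
    assert last is not None
    return last


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
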