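"""Regularity evaluation, read classification, period estimation, consensus.

A read's clustered monomer index is *regular* when all four of the following
hold; failing any makes it *irregular*, and a condition-4 failure
additionally flags an inversion:

1. every cluster has more than one member;
2. consecutive start-position distances within each cluster, divided by the
   median of the pooled distances, lie in the closed band [0.95, 1.05];
3. the head-to-tail gap between adjacent monomers is at most 5 bases;
4. all monomers of a cluster lie on the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np

from tandemhor.cluster import ClusterAssignment, ThresholdSelection
from tandemhor.io import MonomerHitRecord, Read, reverse_complement
from tandemhor._align import encode, global_align_columns

MONOMERIC_IDENTITY_FLOOR = 0.88  # lower end of the threshold scan
_RATIO_EPS = 1e-9


def extract_monomer_seqs(read: Read, hits: Sequence[MonomerHitRecord]) -> list[str]:
    """Monomer sequences in read order, strand-normalized to forward orientation."""
    seqs = []
    for h in hits:
        seg = read.sequence[h.start : h.end]
        seqs.append(seg if h.strand == "+" else reverse_complement(seg))
    return seqs


@dataclass
class ClusterDistances:
    """Start-position spacing per cluster plus the pooled distance set."""

    positions: dict[str, list[int]]
    distances: dict[str, list[int]]
    pooled: list[int]
    median_d: float | None

    @classmethod
    def from_hits(
        cls, hits: Sequence[MonomerHitRecord], assignment: ClusterAssignment
    ) -> "ClusterDistances":
        positions: dict[str, list[int]] = {}
        for ordinal, h in enumerate(hits):
            positions.setdefault(assignment.labels[ordinal], []).append(h.start)
        distances = {
            lab: [b - a for a, b in zip(pos, pos[1:])] for lab, pos in positions.items()
        }
        pooled = [d for lab in sorted(distances) for d in distances[lab]]
        return cls(
            positions=positions,
            distances=distances,
            pooled=pooled,
            median_d=float(median(pooled)) if pooled else None,
        )


@dataclass
class RegularityReport:
    condition1: bool
    condition2: bool
    condition3: bool
    condition4: bool
    failing_monomers: list[int]
    distances: ClusterDistances

    @property
    def regular(self) -> bool:
        return self.condition1 and self.condition2 and self.condition3 and self.condition4


def evaluate_regularity(
    hits: Sequence[MonomerHitRecord],
    assignment: ClusterAssignment,
    max_gap: int = 5,
    ratio_band: tuple[float, float] = (0.95, 1.05),
) -> RegularityReport:
    """Evaluate the four regularity conditions over one read's clustered hits."""
    if len(hits) < 2:
        raise ValueError("evaluate_regularity requires at least 2 hits")
    if any(a.start > b.start for a, b in zip(hits, hits[1:])):
        raise ValueError("hits must be sorted by start")
    if len(assignment.labels) != len(hits):
        raise ValueError("assignment does not cover exactly these hits")

    failing: set[int] = set()
    dist = ClusterDistances.from_hits(hits, assignment)

    # condition 1: no singleton clusters
    singleton_labels = {lab for lab, n in assignment.cluster_sizes.items() if n < 2}
    cond1 = not singleton_labels
    if singleton_labels:
        failing.update(
            i for i, lab in assignment.labels.items() if lab in singleton_labels
        )

    # condition 2: within-cluster spacing consistent with the pooled median
    cond2 = True
    if dist.median_d:
        lo, hi = ratio_band
        ordinal_by_pos = {(assignment.labels[i], hits[i].start): i for i in range(len(hits))}
        for lab, dlist in dist.distances.items():
            pos = dist.positions[lab]
            for i, d in enumerate(dlist):
                ratio = d / dist.median_d
                if not (lo - _RATIO_EPS <= ratio <= hi + _RATIO_EPS):
                    cond2 = False
                    failing.add(ordinal_by_pos[(lab, pos[i])])
                    failing.add(ordinal_by_pos[(lab, pos[i + 1])])

    # condition 3: head-to-tail gaps between adjacent monomers
    cond3 = True
    for k in range(len(hits) - 1):
        gap = hits[k + 1].start - hits[k].end
        if gap > max_gap:
            cond3 = False
            failing.update((k, k + 1))

    # condition 4: consistent orientation within each cluster
    cond4 = True
    for lab in assignment.cluster_sizes:
        members = assignment.members(lab)
        ref_strand = hits[members[0]].strand
        flipped = [i for i in members if hits[i].strand != ref_strand]
        if flipped:
            cond4 = False
            failing.update(flipped)

    return RegularityReport(
        condition1=cond1,
        condition2=cond2,
        condition3=cond3,
        condition4=cond4,
        failing_monomers=sorted(failing),
        distances=dist,
    )


def estimate_period(
    cluster_distances: ClusterDistances, hits: Sequence[MonomerHitRecord]
) -> int:
    """HOR period in monomers: pooled median spacing over median monomer span."""
    if not cluster_distances.pooled:
        raise ValueError("estimate_period requires at least one multi-member cluster")
    span = float(median([h.length for h in hits]))
    assert cluster_distances.median_d is not None
    return int(cluster_distances.median_d / span + 0.5)


def _approximate_period(
    cluster_distances: ClusterDistances, hits: Sequence[MonomerHitRecord]
) -> int | None:
    """Modal per-cluster spacing in monomer units (annotation for irregular reads)."""
    if not cluster_distances.pooled:
        return None
    span = float(median([h.length for h in hits]))
    counts: dict[int, int] = {}
    for d in cluster_distances.pooled:
        k = int(d / span + 0.5)
        counts[k] = counts.get(k, 0) + 1
    modal = max(sorted(counts), key=lambda k: counts[k])
    return modal if modal >= 2 else None


@dataclass
class ReadClassification:
    """Final per-read taxonomy label plus everything the summary table reports."""

    read_id: str
    label: str  # regular | irregular | no-HOR
    inversion_flag: bool = False
    monomeric_flag: bool = False
    transition_flag: bool = False
    hor_period: int | None = None
    approx_period: int | None = None
    selected_threshold: float | None = None
    median_monomer_identity: float | None = None
    read_length: int = 0
    n_monomers: int = 0
    n_clusters: int = 0
    n_nonsat_bases: int = 0
    nonsat_intervals: list[tuple[int, int]] = field(default_factory=list)
    no_hor_reason: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("regular", "irregular", "no-HOR"):
            raise ValueError(f"invalid label {self.label!r}")
        if self.inversion_flag and self.label != "irregular":
            raise ValueError("inversion_flag requires label 'irregular'")
        if self.monomeric_flag and self.label != "no-HOR":
            raise ValueError("monomeric_flag requires label 'no-HOR'")
        if self.hor_period is not None and self.hor_period < 2:
            raise ValueError("hor_period must be >= 2 when present")

    def summary_row(self) -> list[str]:
        from tandemhor.io import MISSING

        if self.hor_period is not None:
            period = str(self.hor_period)
        elif self.approx_period is not None:
            period = f"~{self.approx_period}"
        else:
            period = MISSING
        return [
            self.read_id,
            str(self.read_length),
            str(self.n_monomers),
            str(self.n_clusters) if self.n_monomers else MISSING,
            MISSING if self.selected_threshold is None else f"{self.selected_threshold:.2f}",
            self.label,
            "1" if self.inversion_flag else "0",
            "1" if self.monomeric_flag else "0",
            period,
            MISSING
            if self.median_monomer_identity is None
            else f"{self.median_monomer_identity:.4f}",
            str(self.n_nonsat_bases),
            ";".join(f"{s}-{e}" for s, e in self.nonsat_intervals) or MISSING,
        ]


def classify_read(
    read: Read,
    hits: Sequence[MonomerHitRecord],
    selection: ThresholdSelection | None,
    report: RegularityReport | None,
    transition=None,
    identities: np.ndarray | None = None,
) -> ReadClassification:
    """Assemble the final per-read classification.

    ``selection``/``report`` may be None only when the read has fewer than
    two monomer hits (such reads are no-HOR by definition).  ``identities``
    is the strand-normalized monomer identity matrix, used to decide the
    monomeric sub-category of no-HOR reads.
    """
    n = len(hits)
    identities_list = [h.identity for h in hits if h.identity is not None]
    med_ident = float(median(identities_list)) if identities_list else None
    common = dict(
        read_id=read.id,
        read_length=read.length,
        n_monomers=n,
        median_monomer_identity=med_ident,
        transition_flag=bool(transition.transition_flag) if transition is not None else False,
        n_nonsat_bases=transition.n_nonsat_bases if transition is not None else 0,
        nonsat_intervals=list(transition.qualifying_intervals) if transition is not None else [],
    )

    if n < 2:
        return ReadClassification(
            label="no-HOR", no_hor_reason="too-few-monomers", **common
        )

    if selection is None or report is None:
        raise ValueError("selection and report are required for reads with >= 2 hits")

    monomeric = False
    if identities is not None and identities.shape[0] == n:
        off_diag = identities[~np.eye(n, dtype=bool)]
        monomeric = bool(off_diag.size) and bool(
            np.all(off_diag < MONOMERIC_IDENTITY_FLOOR)
        )

    assignment = selection.assignment
    common["n_clusters"] = assignment.n_clusters
    common["selected_threshold"] = selection.threshold

    if selection.supports_hor:
        if report.regular:
            period = estimate_period(report.distances, hits)
            if period < 2:
                # uniform single-cluster spacing: a tandem of one monomer
                # type, not a multi-monomer unit (an HOR is at least a dimer)
                return ReadClassification(
                    label="no-HOR",
                    monomeric_flag=monomeric,
                    no_hor_reason="single-monomer-period",
                    **common,
                )
            return ReadClassification(label="regular", hor_period=period, **common)
        return ReadClassification(
            label="irregular",
            inversion_flag=not report.condition4,
            approx_period=_approximate_period(report.distances, hits),
            **common,
        )

    # no threshold supported HOR inference: irregular if the lowest-threshold
    # clustering still shows repeated structure, no-HOR otherwise
    if len(assignment.multi_member_labels) >= 2:
        return ReadClassification(
            label="irregular",
            inversion_flag=not report.condition4,
            approx_period=_approximate_period(report.distances, hits),
            **common,
        )
    return ReadClassification(
        label="no-HOR",
        monomeric_flag=monomeric,
        no_hor_reason="monomeric" if monomeric else "single-copy-or-incomplete",
        **common,
    )


def _majority_consensus(seqs: list[str]) -> str:
    """Star alignment to the first member; column-wise majority vote.

    Ties prefer the reference base, then the lexicographically smallest
    symbol; a gap majority drops the column.
    """
    ref = seqs[0]
    if len(seqs) == 1:
        return ref
    votes: list[dict[str, int]] = [{ref[i]: 1} for i in range(len(ref))]
    ref_enc = encode(ref)
    for other in seqs[1:]:
        covered = [False] * len(ref)
        for ri, oi in global_align_columns(ref_enc, encode(other)):
            if ri >= 0:
                sym = other[oi] if oi >= 0 else "-"
                votes[ri][sym] = votes[ri].get(sym, 0) + 1
                covered[ri] = True
    out = []
    for i, v in enumerate(votes):
        best = max(v.values())
        winners = sorted(sym for sym, c in v.items() if c == best)
        pick = ref[i] if ref[i] in winners else winners[0]
        if pick != "-":
            out.append(pick)
    return "".join(out)


def hor_consensus(
    read: Read,
    hits: Sequence[MonomerHitRecord],
    assignment: ClusterAssignment,
    classification: ReadClassification,
) -> tuple[list[tuple[str, str]], str]:
    """Per-cluster majority consensi plus the concatenated full-unit consensus.

    Only defined for regular reads; cluster order is order of first
    appearance along the read (= within-unit order for a regular read).
    """
    if classification.label != "regular":
        raise ValueError("hor_consensus is only defined for regular reads")
    seqs = extract_monomer_seqs(read, hits)
    first_seen: dict[str, int] = {}
    for ordinal in sorted(assignment.labels):
        first_seen.setdefault(assignment.labels[ordinal], ordinal)
    per_cluster: list[tuple[str, str]] = []
    for lab in sorted(first_seen, key=first_seen.get):
        members = assignment.members(lab)
        per_cluster.append((lab, _majority_consensus([seqs[i] for i in members])))
    unit = "".join(cons for _, cons in per_cluster)
    return per_cluster, unit
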