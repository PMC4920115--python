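"""Uncovered-interval analysis: non-satellite stretches and transition regions.

A read's uncovered intervals are the complement of the union of its monomer
hits.  Any single uncovered interval of at least ``min_nonsat_length`` bases
(default 1 kb) marks the read as containing a transition into non-satellite
sequence; qualifying intervals are exported as FASTA + BED for external
repeat-library annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from tandemhor.io import MonomerHitRecord, Read, write_bed, write_fasta

DEFAULT_MIN_NONSAT_LENGTH = 1000


@dataclass
class TransitionSummary:
    read_id: str
    uncovered_intervals: list[tuple[int, int]]
    n_nonsat_bases: int
    transition_flag: bool
    min_nonsat_length: int = DEFAULT_MIN_NONSAT_LENGTH

    @property
    def qualifying_intervals(self) -> list[tuple[int, int]]:
        return [
            (s, e)
            for s, e in self.uncovered_intervals
            if e - s >= self.min_nonsat_length
        ]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def uncovered_regions(
    read: Read,
    hits: Sequence[MonomerHitRecord],
    min_nonsat_length: int = DEFAULT_MIN_NONSAT_LENGTH,
) -> TransitionSummary:
    """Complement of the hit-interval union within [0, read length)."""
    for h in hits:
        if h.end > read.length:
            raise ValueError(f"hit [{h.start}, {h.end}) exceeds read length {read.length}")
    covered = _merge_intervals([(h.start, h.end) for h in hits])
    uncovered: list[tuple[int, int]] = []
    cursor = 0
    for s, e in covered:
        if s > cursor:
            uncovered.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < read.length:
        uncovered.append((cursor, read.length))
    total = sum(e - s for s, e in uncovered)
    flag = any(e - s >= min_nonsat_length for s, e in uncovered)
    return TransitionSummary(
        read_id=read.id,
        uncovered_intervals=uncovered,
        n_nonsat_bases=total,
        transition_flag=flag,
        min_nonsat_length=min_nonsat_length,
    )


def export_nonsatellite(
    read: Read, summary: TransitionSummary, fasta_path, bed_path
) -> None:
    """Write qualifying (>= min length) intervals as FASTA and BED.

    FASTA ids are ``read_id:start-end`` (0-based half-open, matching the BED).
    """
    if not summary.transition_flag:
        raise ValueError("export_nonsatellite requires transition_flag to be set")
    qualifying = summary.qualifying_intervals
    write_fasta(
        (
            (f"{read.id}:{s}-{e}", read.sequence[s:e])
            for s, e in qualifying
        ),
        fasta_path,
    )
    write_bed(((read.id, s, e) for s, e in qualifying), bed_path)
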