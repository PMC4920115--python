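"""Built-in monomer detector.

Locates occurrences of training monomers on both strands of a read using
exact k-mer seeding followed by a fitting alignment of the model against the
seeded window.  The external profile-HMM front end
(:func:`tandemhor.io.parse_external_hits`) is interchangeable with this one;
everything downstream consumes plain :class:`~tandemhor.io.MonomerHitRecord`
lists and does not care which produced them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from tandemhor._align import encode, fit_align
from tandemhor.io import MonomerHitRecord, Read, normalize_sequence, reverse_complement


@dataclass(frozen=True)
class MonomerModel:
    """A training-set monomer (consensus of the basic repeat unit, ~171 bp)."""

    model_id: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"model {self.model_id!r} has an empty consensus")
        object.__setattr__(self, "consensus", normalize_sequence(self.consensus))


@dataclass
class DetectionConfig:
    """Tunables for the built-in detector.

    ``min_length`` is the minimum emitted hit length (default 150 bases).
    ``min_model_identity`` is the acceptance floor for the hit-vs-model
    alignment identity; the profile-search score cutoff it stands in for is
    not fixed by the method, so it is exposed here.
    """

    min_length: int = 150
    min_model_identity: float = 0.70
    max_overlap_fraction: float = 0.1
    seed_k: int = 12
    min_seed_votes: int = 3
    pad: int = 25

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        for name in ("min_model_identity", "max_overlap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def load_models(path) -> list[MonomerModel]:
    """Load a monomer training set from FASTA."""
    from tandemhor.io import read_fasta

    return [MonomerModel(model_id=r.id, consensus=r.sequence) for r in read_fasta(path)]


def _seed_index(models: Sequence[MonomerModel], k: int):
    """Map k-mer -> [(model_ordinal, strand, offset_in_oriented_model)]."""
    index: dict[str, list[tuple[int, str, int]]] = {}
    oriented: list[dict[str, str]] = []
    for mi, model in enumerate(models):
        oriented.append({"+": model.consensus, "-": reverse_complement(model.consensus)})
        for strand in ("+", "-"):
            seq = oriented[mi][strand]
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((mi, strand, off))
    return index, oriented


def _candidate_starts(
    read_seq: str, index, k: int, min_votes: int, merge_radius: int
) -> list[tuple[int, str, int, int]]:
    """Vote for approximate monomer start positions per (model, strand).

    Returns (model_ordinal, strand, representative_start, votes) sorted by
    representative start.
    """
    votes: dict[tuple[int, str], list[int]] = {}
    for pos in range(len(read_seq) - k + 1):
        entries = index.get(read_seq[pos : pos + k])
        if not entries:
            continue
        for mi, strand, off in entries:
            votes.setdefault((mi, strand), []).append(pos - off)
    candidates: list[tuple[int, str, int, int]] = []
    for (mi, strand), starts in votes.items():
        starts.sort()
        group = [starts[0]]
        for s in starts[1:]:
            if s - group[-1] <= merge_radius:
                group.append(s)
            else:
                if len(group) >= min_votes:
                    candidates.append((mi, strand, group[len(group) // 2], len(group)))
                group = [s]
        if len(group) >= min_votes:
            candidates.append((mi, strand, group[len(group) // 2], len(group)))
    candidates.sort(key=lambda c: (c[2], c[1], c[0]))
    return candidates


def detect_monomers(
    read: Read, models: Sequence[MonomerModel], config: DetectionConfig | None = None
) -> list[MonomerHitRecord]:
    """Detect monomer occurrences on both strands of ``read``.

    Candidate loci are seeded by exact ``seed_k``-mers shared with a model
    (in either orientation), each candidate is refined by a fitting alignment
    of the oriented model against the padded window, and surviving hits are
    made non-overlapping greedily by score (ties: leftmost start, then
    lexicographic model id).  The result is sorted by start; a read without
    detectable monomers yields an empty list.
    """
    if config is None:
        config = DetectionConfig()
    if not models:
        raise ValueError("detect_monomers requires at least one model")

    index, oriented = _seed_index(models, config.seed_k)
    merge_radius = max(20, min(len(m.consensus) for m in models) // 4)
    candidates = _candidate_starts(
        read.sequence, index, config.seed_k, config.min_seed_votes, merge_radius
    )
    read_arr = encode(read.sequence)
    L = read.length

    raw: list[MonomerHitRecord] = []
    for mi, strand, rep_start, _votes in candidates:
        model_seq = oriented[mi][strand]
        seg_lo = max(0, rep_start - config.pad)
        seg_hi = min(L, rep_start + len(model_seq) + config.pad)
        if seg_hi - seg_lo < config.min_length:
            continue
        score, s0, s1, matches, cols = fit_align(
            encode(model_seq), read_arr[seg_lo:seg_hi]
        )
        start, end = seg_lo + s0, seg_lo + s1
        if end - start < config.min_length or cols == 0:
            continue
        identity = matches / cols
        if identity < config.min_model_identity:
            continue
        raw.append(
            MonomerHitRecord(
                read_id=read.id,
                start=start,
                end=end,
                strand=strand,
                model_id=models[mi].model_id,
                score=float(score),
                identity=identity,
            )
        )

    accepted = _resolve_overlaps(raw, config.max_overlap_fraction)
    accepted.sort(key=lambda h: (h.start, h.end))
    return accepted


def _resolve_overlaps(
    hits: list[MonomerHitRecord], max_overlap_fraction: float
) -> list[MonomerHitRecord]:
    """Greedy by descending score; ties by leftmost start then model id."""
    order = sorted(hits, key=lambda h: (-h.score, h.start, h.model_id))
    accepted: list[MonomerHitRecord] = []
    for h in order:
        ok = True
        for a in accepted:
            overlap = min(h.end, a.end) - max(h.start, a.start)
            if overlap <= 0:
                continue
            shorter = min(h.length, a.length)
            if overlap > max_overlap_fraction * shorter:
                ok = False
                break
        if ok:
            accepted.append(h)
    return accepted


def monomer_index(hits: Sequence[MonomerHitRecord]) -> tuple[int, ...]:
    """Ordered index of monomer start positions for one read.

    All hits must come from a single read; starts must be distinct.
    """
    if not hits:
        return ()
    read_ids = {h.read_id for h in hits}
    if len(read_ids) != 1:
        raise ValueError(f"monomer_index: hits span multiple reads: {sorted(read_ids)}")
    starts = sorted(h.start for h in hits)
    for a, b in zip(starts, starts[1:]):
        if a == b:
            raise ValueError(f"monomer_index: duplicate start position {a}")
    return tuple(starts)
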