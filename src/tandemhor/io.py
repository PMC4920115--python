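"""Readers and writers for every external representation the pipeline touches.

Conventions (applied once, here, at the parse boundary):

* coordinates are 0-based, half-open, on the forward strand of the read;
* sequences are uppercased and characters outside ``{A, C, G, T, N}`` are
  mapped to ``N``;
* the per-read summary is a TSV with a header line and ``.`` for missing
  values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in _VALID else c) for c in map(chr, range(256))}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA or hit-table input."""


@dataclass(frozen=True)
class Read:
    """A long read: identifier plus an uppercase A/C/G/T/N sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Read id must be non-empty")
        if not self.sequence:
            raise ValueError(f"Read {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MonomerHitRecord:
    """One detected monomer occurrence on a read (forward-strand coordinates)."""

    read_id: str
    start: int
    end: int
    strand: str
    model_id: str
    score: float
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid hit interval [{self.start}, {self.end}) on {self.read_id}"
            )
        if self.identity is not None and not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map everything outside {A,C,G,T,N} to N."""
    return seq.upper().translate(_NORMALIZE)


def iter_fasta(path: str | Path) -> Iterator[Read]:
    """Stream Reads from a FASTA file, normalizing sequences.

    Raises :class:`FastaFormatError` on an empty file, a file that does not
    start with a header, or a record with no sequence; the message names the
    offending line number.
    """
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()
    n_lines = 0

    def finish() -> Read:
        assert header is not None
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(
                f"record {header!r} (line {header_line}) has no sequence"
            )
        if header in seen:
            raise FastaFormatError(
                f"duplicate read id {header!r} at line {header_line}"
            )
        seen.add(header)
        return Read(id=header, sequence=normalize_sequence(seq))

    with _open_text(path) as fh:
        for n_lines, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    yield finish()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError(f"empty FASTA header at line {n_lines}")
                header_line = n_lines
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {n_lines}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    if header is None:
        raise FastaFormatError(f"{path}: empty file (no FASTA records)")
    yield finish()


def read_fasta(path: str | Path) -> list[Read]:
    """Read all records of a FASTA file into memory (see :func:`iter_fasta`)."""
    return list(iter_fasta(path))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


SUMMARY_COLUMNS = (
    "read_id",
    "read_length",
    "n_monomers",
    "n_clusters",
    "selected_threshold",
    "classification",
    "inversion_flag",
    "monomeric_flag",
    "hor_period",
    "median_monomer_identity",
    "n_nonsat_bases",
    "nonsat_intervals",
)

MISSING = "."


def write_read_summary(classifications: Sequence, path: str | Path) -> None:
    """Write the per-read summary TSV (one row per read, input order)."""
    if not classifications:
        raise ValueError("write_read_summary requires at least one classification")
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for c in classifications:
            fh.write("\t".join(c.summary_row()) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write (name, start, end) triples as BED3 (0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for name, start, end in intervals:
            fh.write(f"{name}\t{start}\t{end}\n")


def parse_external_hits(path: str | Path, min_length: int = 150) -> list[MonomerHitRecord]:
    """Parse the tabular output of an external profile-HMM nucleotide search.

    Expects the whitespace-delimited one-row-per-hit table with columns
    (target, accession, model, accession, model-from, model-to, ali-from,
    ali-to, env-from, env-to, target-length, strand, E-value, score, bias,
    description).  Alignment coordinates are 1-based inclusive and reversed
    on minus-strand rows; they are converted here to 0-based half-open
    forward-strand intervals.  Rows spanning fewer than ``min_length`` bases
    are discarded.
    """
    hits: list[MonomerHitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 14:
                raise FastaFormatError(
                    f"{path}: row {lineno} has {len(fields)} columns, expected >= 14"
                )
            try:
                target = fields[0]
                model = fields[2]
                alifrom = int(fields[6])
                alito = int(fields[7])
                strand = fields[11]
                score = float(fields[13])
            except ValueError as exc:
                raise FastaFormatError(f"{path}: unparsable row {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise FastaFormatError(
                    f"{path}: row {lineno}: invalid strand {strand!r}"
                )
            lo, hi = (alifrom, alito) if alifrom <= alito else (alito, alifrom)
            start, end = lo - 1, hi  # 1-based inclusive -> 0-based half-open
            if end - start < min_length:
                continue
            hits.append(
                MonomerHitRecord(
                    read_id=target,
                    start=start,
                    end=end,
                    strand=strand,
                    model_id=model,
                    score=score,
                )
            )
    return hits


def write_hits_table(hits: Sequence[MonomerHitRecord], path: str | Path) -> None:
    """Write hits as a simple TSV (the package's own hit interchange format)."""
    with _open_text(path, "wt") as fh:
        fh.write("read_id\tstart\tend\tstrand\tmodel_id\tscore\tidentity\n")
        for h in hits:
            ident = MISSING if h.identity is None else f"{h.identity:.6f}"
            fh.write(
                f"{h.read_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.model_id}"
                f"\t{h.score:g}\t{ident}\n"
            )


def read_hits_table(path: str | Path) -> list[MonomerHitRecord]:
    """Read the TSV written by :func:`write_hits_table`."""
    hits: list[MonomerHitRecord] = []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise FastaFormatError(f"{path}: not a tandemhor hits table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise FastaFormatError(f"{path}: row {lineno}: expected 7 columns")
            hits.append(
                MonomerHitRecord(
                    read_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[3],
                    model_id=f[4],
                    score=float(f[5]),
                    identity=None if f[6] == MISSING else float(f[6]),
                )
            )
    return hits
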