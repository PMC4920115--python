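"""End-to-end per-read orchestration and batch output writing."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from tandemhor import __version__ as _version
from tandemhor.cluster import select_threshold, identity_matrix
from tandemhor.detect import DetectionConfig, MonomerModel, detect_monomers
from tandemhor.hor import (
    ReadClassification,
    classify_read,
    evaluate_regularity,
    extract_monomer_seqs,
    hor_consensus,
)
from tandemhor.io import (
    MonomerHitRecord,
    Read,
    iter_fasta,
    parse_external_hits,
    read_hits_table,
    write_bed,
    write_fasta,
    write_hits_table,
    write_read_summary,
)
from tandemhor.transitions import TransitionSummary, uncovered_regions


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    threshold_high: float = 0.98
    threshold_low: float = 0.88
    threshold_step: float = 0.01
    condition2_band: tuple[float, float] = (0.95, 1.05)
    max_gap: int = 5
    min_nonsat_length: int = 1000
    min_read_length: int = 2000

    def __post_init__(self) -> None:
        if self.threshold_high < self.threshold_low:
            raise ValueError("threshold_high must be >= threshold_low")
        lo, hi = self.condition2_band
        if not (lo < 1.0 < hi):
            raise ValueError("condition2_band must bracket 1.0")

    @property
    def threshold_grid(self) -> tuple[float, ...]:
        grid = []
        t = self.threshold_high
        while t >= self.threshold_low - 1e-9:
            grid.append(round(t, 6))
            t -= self.threshold_step
        return tuple(grid)


@dataclass
class PerReadResult:
    read: Read
    hits: list[MonomerHitRecord]
    classification: ReadClassification
    transition: TransitionSummary
    consensus: list[tuple[str, str]] = field(default_factory=list)  # FASTA records


def process_read(
    read: Read,
    models: Sequence[MonomerModel] | None = None,
    hits: Sequence[MonomerHitRecord] | None = None,
    config: PipelineConfig | None = None,
) -> PerReadResult:
    """Run detection (unless hits are given), clustering, classification and
    transition analysis for one read."""
    if config is None:
        config = PipelineConfig()
    if (models is None) == (hits is None):
        raise ValueError("provide exactly one of models / hits")

    if hits is None:
        hits = detect_monomers(read, models, config.detection)
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    transition = uncovered_regions(read, hits, config.min_nonsat_length)

    if len(hits) < 2:
        classification = classify_read(read, hits, None, None, transition)
        return PerReadResult(read, list(hits), classification, transition)

    seqs = extract_monomer_seqs(read, hits)
    matrix = identity_matrix(seqs)
    selection = select_threshold(
        seqs, read_id=read.id, matrix=matrix, grid=config.threshold_grid
    )
    report = evaluate_regularity(
        hits,
        selection.assignment,
        max_gap=config.max_gap,
        ratio_band=config.condition2_band,
    )
    classification = classify_read(
        read, hits, selection, report, transition, identities=matrix
    )

    consensus: list[tuple[str, str]] = []
    if classification.label == "regular":
        per_cluster, unit = hor_consensus(read, hits, selection.assignment, classification)
        consensus = [
            (f"{read.id}/cluster_{lab}", cons) for lab, cons in per_cluster
        ] + [(f"{read.id}/unit", unit)]
    return PerReadResult(read, list(hits), classification, transition, consensus)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic(path: Path):
    """Return a temp path next to ``path``; caller renames when done."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    return Path(tmp)


def run_pipeline(
    reads_path: str | Path,
    monomers_path: str | Path | None = None,
    hits_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path = ".",
    hits_format: str = "tblout",
) -> list[PerReadResult]:
    """Process every read of a FASTA file and write the batch outputs.

    Outputs under ``outdir``: ``summary.tsv`` (one row per processed read),
    ``consensus.fasta`` (cluster + unit consensi of regular reads),
    ``monomers.tsv`` (all accepted monomer hits), ``transitions.bed`` /
    ``transitions.fasta`` (qualifying non-satellite intervals) and
    ``manifest.json``.  Files are written to temp names and renamed, so a
    crash never leaves a partial output in place.
    """
    if config is None:
        config = PipelineConfig()
    if (monomers_path is None) == (hits_path is None):
        raise ValueError("provide exactly one of monomers_path / hits_path")

    models = None
    hits_by_read: dict[str, list[MonomerHitRecord]] = {}
    if monomers_path is not None:
        from tandemhor.detect import load_models

        models = load_models(monomers_path)
    else:
        parsed = (
            parse_external_hits(hits_path, min_length=config.detection.min_length)
            if hits_format == "tblout"
            else read_hits_table(hits_path)
        )
        for h in parsed:
            hits_by_read.setdefault(h.read_id, []).append(h)

    results: list[PerReadResult] = []
    n_seen = 0
    for read in iter_fasta(reads_path):
        n_seen += 1
        if read.length < config.min_read_length:
            continue
        if models is not None:
            results.append(process_read(read, models=models, config=config))
        else:
            results.append(
                process_read(read, hits=hits_by_read.get(read.id, []), config=config)
            )
    if not results:
        raise ValueError(
            f"no reads passed the min_read_length={config.min_read_length} filter "
            f"({n_seen} read(s) seen)"
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, writer) -> None:
        target = outdir / name
        tmp = _atomic(target)
        try:
            writer(tmp)
            os.replace(tmp, target)
        finally:
            tmp.unlink(missing_ok=True)

    _write(
        "summary.tsv",
        lambda p: write_read_summary([r.classification for r in results], p),
    )
    _write(
        "consensus.fasta",
        lambda p: write_fasta(
            (rec for r in results for rec in r.consensus), p
        ),
    )
    _write(
        "monomers.tsv",
        lambda p: write_hits_table([h for r in results for h in r.hits], p),
    )
    transition_rows = [
        (r.read.id, s, e)
        for r in results
        if r.transition.transition_flag
        for s, e in r.transition.qualifying_intervals
    ]
    _write("transitions.bed", lambda p: write_bed(transition_rows, p))
    _write(
        "transitions.fasta",
        lambda p: write_fasta(
            (
                (f"{r.read.id}:{s}-{e}", r.read.sequence[s:e])
                for r in results
                if r.transition.transition_flag
                for s, e in r.transition.qualifying_intervals
            ),
            p,
        ),
    )

    manifest = {
        "tool": "tandemhor",
        "version": _version,
        "config": _config_dict(config),
        "inputs": {
            "reads": {"path": str(reads_path), "sha256": _sha256(reads_path)},
        },
        "n_reads_seen": n_seen,
        "n_reads_processed": len(results),
    }
    if monomers_path is not None:
        manifest["inputs"]["monomers"] = {
            "path": str(monomers_path),
            "sha256": _sha256(monomers_path),
        }
    else:
        manifest["inputs"]["hits"] = {
            "path": str(hits_path),
            "sha256": _sha256(hits_path),
            "format": hits_format,
        }
    _write(
        "manifest.json",
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2) + "\n"),
    )
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["threshold_grid"] = list(config.threshold_grid)
    return d
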