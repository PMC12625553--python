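"""Extraction of aligned regions (with flanking padding) or whole contigs
from the source FASTA files referenced by a results table.

Coordinates follow the BLAST convention: 1-based inclusive, with a
minus-strand subject hit encoded by ``sstart > send``. Padding is oriented:
``pad_up`` extends the 5′ side of the hit *in hit orientation*, and
minus-strand output is reverse-complemented so extracted genes read forward.
Intervals are clamped to the contig; the header records both the requested
and the applied interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .blast import HitRecord, read_results_csv
from .fasta_io import CANONICAL_EXTENSIONS, SequenceRecord, read_fasta, write_fasta

logger = logging.getLogger("blastkit")


class ExtractionError(ValueError):
    """Raised for unknown contigs, ambiguous sources, or malformed coordinates."""


@dataclass
class ExtractionSpec:
    """What to pull from the source FASTA files.

    ``pad_up``/``pad_down`` are base pairs (residues for protein subjects)
    added on the 5′/3′ side of the hit in hit orientation; both must be zero
    in contig mode.
    """

    results: Path
    fasta_dir: Path
    pad_up: int = 0
    pad_down: int = 0
    mode: str = "region"  # "region" | "contig"

    def __post_init__(self) -> None:
        if self.pad_up < 0 or self.pad_down < 0:
            raise ExtractionError("padding must be non-negative")
        if self.mode == "contig" and (self.pad_up or self.pad_down):
            raise ExtractionError("padding does not apply in contig mode")


@dataclass
class ExtractedRegion:
    """One extracted slice, in hit orientation."""

    database: str
    contig: str
    requested: tuple[int, int]
    applied: tuple[int, int]
    strand: str  # "+" | "-"
    residues: str

    def to_record(self) -> SequenceRecord:
        req = f"{self.requested[0]}-{self.requested[1]}"
        app = f"{self.applied[0]}-{self.applied[1]}"
        return SequenceRecord(
            id=f"{self.database}_{self.contig}_{app}",
            description=f"strand={self.strand} requested={req} applied={app}",
            residues=self.residues,
            molecule="nucleotide",
        )


def reverse_complement(residues: str) -> str:
    return str(Seq(residues).reverse_complement())


def locate_source_fasta(database_name: str, fasta_dir: str | Path) -> Path:
    """Find the unique FASTA file in ``fasta_dir`` whose stem is the database name."""
    fasta_dir = Path(fasta_dir)
    if not fasta_dir.is_dir():
        raise ExtractionError(f"FASTA directory does not exist: {fasta_dir}")
    candidates = [
        fasta_dir / f"{database_name}{ext}{gz}"
        for ext in CANONICAL_EXTENSIONS
        for gz in ("", ".gz")
        if (fasta_dir / f"{database_name}{ext}{gz}").exists()
    ]
    if not candidates:
        raise ExtractionError(
            f"no FASTA file with stem {database_name!r} found in {fasta_dir}"
        )
    if len(candidates) > 1:
        raise ExtractionError(
            f"ambiguous source for database {database_name!r}: "
            + ", ".join(c.name for c in candidates)
        )
    return candidates[0]


def extract_hit(
    hit: HitRecord, spec: ExtractionSpec, contigs: Mapping[str, SequenceRecord]
) -> ExtractedRegion:
    """Slice the subject interval of one hit, padded and clamped.

    Plus-strand hits (sstart ≤ send) yield ``[sstart − pad_up, send + pad_down]``;
    minus-strand hits yield the reverse complement of the clamped
    ``[send − pad_down, sstart + pad_up]`` so pad_up sits on the hit's 5′ side.
    """
    if hit.sseqid not in contigs:
        raise ExtractionError(
            f"contig {hit.sseqid!r} not found in source for database {hit.database!r}"
        )
    contig = contigs[hit.sseqid]
    n = len(contig.residues)
    minus = hit.sstart > hit.send
    lo, hi = (hit.send, hit.sstart) if minus else (hit.sstart, hit.send)
    if not 1 <= lo <= hi:
        raise ExtractionError(f"malformed subject coordinates: {hit.sstart}..{hit.send}")
    if minus:
        requested = (lo - spec.pad_down, hi + spec.pad_up)
    else:
        requested = (lo - spec.pad_up, hi + spec.pad_down)
    applied = (max(1, requested[0]), min(n, requested[1]))
    slice_ = contig.residues[applied[0] - 1: applied[1]]
    return ExtractedRegion(
        database=hit.database,
        contig=hit.sseqid,
        requested=requested,
        applied=applied,
        strand="-" if minus else "+",
        residues=reverse_complement(slice_) if minus else slice_,
    )


def extract_contig(hit: HitRecord, contigs: Mapping[str, SequenceRecord]) -> SequenceRecord:
    """Return the full contig a hit landed on, unmodified."""
    if hit.sseqid not in contigs:
        raise ExtractionError(
            f"contig {hit.sseqid!r} not found in source for database {hit.database!r}"
        )
    return contigs[hit.sseqid]


def _load_sources(hits: Sequence[HitRecord], fasta_dir: Path) -> dict[str, dict[str, SequenceRecord]]:
    sources: dict[str, dict[str, SequenceRecord]] = {}
    for db in sorted({h.database for h in hits}):
        path = locate_source_fasta(db, fasta_dir)
        sources[db] = {r.id: r for r in read_fasta(path)}
    return sources


def extract_regions(spec: ExtractionSpec, out: str | Path) -> Path:
    """Region mode over a whole results table: one multi-FASTA for the run.

    Record order follows the canonical table sort of the input CSV.
    """
    hits = read_results_csv(spec.results)
    sources = _load_sources(hits, Path(spec.fasta_dir))
    regions = [extract_hit(h, spec, sources[h.database]) for h in hits]
    return write_fasta((r.to_record() for r in regions), out)


def extract_contigs(spec: ExtractionSpec, out_dir: str | Path) -> list[Path]:
    """Contig mode: one multi-FASTA per database, each contig written once."""
    hits = read_results_csv(spec.results)
    sources = _load_sources(hits, Path(spec.fasta_dir))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for db in sorted(sources):
        seen: set[str] = set()
        records: list[SequenceRecord] = []
        for hit in hits:
            if hit.database == db and hit.sseqid not in seen:
                records.append(extract_contig(hit, sources[db]))
                seen.add(hit.sseqid)
        if records:
            outputs.append(write_fasta(records, out_dir / f"{db}_contigs.fasta"))
    return outputs
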