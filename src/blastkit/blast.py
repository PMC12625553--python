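"""BLAST+ orchestration: batch database creation, program dispatch, parallel
query execution, and curation of unified results tables.

The program for each query×database pairing follows the standard dispatch
rule: nucleotide database + amino-acid query → tblastn; protein database +
amino-acid query → blastp; nucleotide database + ``--nucleotide-query`` →
blastn. Hits are collected with a custom tabular format that appends qlen,
sframe and the aligned subject string to the standard 12 fields; three CSV
tables are curated from them:

* ``all_results.csv`` — every hit, regardless of inclusion thresholds;
* ``all_filtered_results.csv`` — hits passing identity/coverage/E-value
  thresholds (defaults 90% / 75% / 1e-5, inclusive comparisons);
* ``filtered_results.csv`` — the strongest match per query×database pairing.
"""

from __future__ import annotations

import csv
import logging
import shutil
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .fasta_io import (
    FastaCollection,
    detect_molecule_type,
    sanitize_collection,
    sanitize_filename,
)

logger = logging.getLogger("blastkit")

#: The 14 BLAST fields carried verbatim in the results tables, in order.
BLAST_FIELDS = (
    "qseqid", "sseqid", "pident", "evalue", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "bitscore", "qlen", "sframe",
)
#: Full column order of the curated CSV tables.
TABLE_COLUMNS = BLAST_FIELDS + ("qcov", "query_file", "database")

#: Tabular output requested from the search programs (subject string last,
#: consumed in memory by the motif engine and never written to the tables).
_OUTFMT = "6 " + " ".join(BLAST_FIELDS) + " sseq"

REQUIRED_BINARIES = ("makeblastdb", "blastn", "blastp", "tblastn")

_INT_FIELDS = {"length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send", "qlen", "sframe"}
_FLOAT_FIELDS = {"pident", "evalue", "bitscore"}


class BlastError(RuntimeError):
    """Raised for orchestration failures (missing binaries, bad inputs)."""


class MissingBinaryError(BlastError):
    """An external BLAST+ binary is not on PATH."""


def require_binaries(names: Iterable[str]) -> None:
    missing = [n for n in names if shutil.which(n) is None]
    if missing:
        raise MissingBinaryError(
            f"required BLAST+ binaries not found on PATH: {', '.join(missing)}"
        )


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusion thresholds for the filtered tables (inclusive comparisons)."""

    min_identity: float = 90.0
    min_coverage: float = 75.0
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValueError(f"min_identity must be in [0, 100], got {self.min_identity}")
        if not 0 <= self.min_coverage <= 100:
            raise ValueError(f"min_coverage must be in [0, 100], got {self.min_coverage}")
        if self.max_evalue <= 0:
            raise ValueError(f"max_evalue must be > 0, got {self.max_evalue}")

    def accepts(self, hit: "HitRecord") -> bool:
        return (
            hit.pident >= self.min_identity
            and hit.qcov >= self.min_coverage
            and hit.evalue <= self.max_evalue
        )


@dataclass(frozen=True)
class BlastDatabase:
    """One formatted BLAST database built from a single FASTA file."""

    name: str
    db_type: str  # "nucl" | "prot"
    prefix: Path
    source: Path


@dataclass
class HitRecord:
    """One alignment hit: the 14 reported BLAST fields plus computed query
    coverage, the aligned subject residues, and pairing provenance.

    ``raw`` preserves the search tool's own text for each field so the CSV
    tables mirror it verbatim; ``program`` is in-memory provenance only.
    """

    qseqid: str
    sseqid: str
    pident: float
    evalue: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    bitscore: float
    qlen: int
    sframe: int
    subject_residues: str = ""
    query_file: str = ""
    database: str = ""
    program: str | None = None
    raw: dict[str, str] | None = None

    @property
    def qcov(self) -> float:
        return compute_query_coverage(self.qstart, self.qend, self.qlen)

    @property
    def degapped_subject(self) -> str:
        return self.subject_residues.replace("-", "").upper()

    @classmethod
    def from_tabular_line(
        cls, line: str, query_file: str, database: str, program: str
    ) -> "HitRecord":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(BLAST_FIELDS) + 1:
            raise BlastError(f"unexpected tabular line ({len(parts)} fields): {line!r}")
        raw = dict(zip(BLAST_FIELDS, parts))
        kwargs = {
            name: (int(val) if name in _INT_FIELDS
                   else float(val) if name in _FLOAT_FIELDS else val)
            for name, val in raw.items()
        }
        return cls(
            subject_residues=parts[-1],
            query_file=query_file,
            database=database,
            program=program,
            raw=raw,
            **kwargs,
        )

    def to_csv_row(self) -> list[str]:
        raw = self.raw or {}
        values = [raw.get(f, _default_format(f, getattr(self, f))) for f in BLAST_FIELDS]
        return values + [f"{self.qcov:.2f}", self.query_file, self.database]


def _default_format(name: str, value) -> str:
    if name in _FLOAT_FIELDS:
        return repr(float(value)) if name == "evalue" else f"{value:g}"
    return str(value)


def compute_query_coverage(qstart: int, qend: int, qlen: int) -> float:
    """Query coverage as 100 × (qend − qstart + 1) / qlen, rounded to 2 decimals."""
    if not 1 <= qstart <= qend <= qlen:
        raise ValueError(
            f"invalid coordinates: expected 1 <= qstart <= qend <= qlen, "
            f"got qstart={qstart}, qend={qend}, qlen={qlen}"
        )
    return round(100.0 * (qend - qstart + 1) / qlen, 2)


def select_program(db_type: str, nucleotide_query: bool = False) -> str:
    """Dispatch rule: nucl+protein→tblastn, prot+protein→blastp, nucl+nucl→blastn."""
    if db_type == "nucl":
        return "blastn" if nucleotide_query else "tblastn"
    if db_type == "prot":
        if nucleotide_query:
            raise BlastError(
                "no supported program for a nucleotide query against a protein database"
            )
        return "blastp"
    raise BlastError(f"unknown database type {db_type!r}")


def filter_hits(hits: Iterable[HitRecord], thresholds: ThresholdSet) -> list[HitRecord]:
    """Retain exactly the hits meeting all three thresholds (inclusive)."""
    return [h for h in hits if thresholds.accepts(h)]


def strongest_matches(filtered: Iterable[HitRecord]) -> list[HitRecord]:
    """At most one hit per (query_file, database) pairing.

    Selection: maximal bitscore; ties broken by minimal E-value, then maximal
    percent identity, then lexicographically smallest sseqid.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for hit in filtered:
        key = (hit.query_file, hit.database)
        champ = best.get(key)
        if champ is None or _strength(hit) > _strength(champ):
            best[key] = hit
    return _canonical_sort(best.values())


def _strength(h: HitRecord):
    return (h.bitscore, -h.evalue, h.pident, _ReverseStr(h.sseqid))


class _ReverseStr(str):
    """Orders lexicographically descending so max() picks the smallest sseqid."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _canonical_sort(hits: Iterable[HitRecord]) -> list[HitRecord]:
    return sorted(
        hits,
        key=lambda h: (h.query_file, h.database, h.evalue, -h.bitscore, h.sseqid, h.sstart),
    )


@dataclass
class ResultsSet:
    """Curated hits across all query×database pairings."""

    all_hits: list[HitRecord]
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    failures: list[str] = field(default_factory=list)

    @property
    def filtered_hits(self) -> list[HitRecord]:
        return filter_hits(self.all_hits, self.thresholds)

    @property
    def strongest(self) -> list[HitRecord]:
        return strongest_matches(self.filtered_hits)

    def write_tables(self, out_dir: str | Path, strongest: bool = False) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {
            "all": _write_csv(_canonical_sort(self.all_hits), out_dir / "all_results.csv"),
            "filtered": _write_csv(
                _canonical_sort(self.filtered_hits), out_dir / "all_filtered_results.csv"
            ),
        }
        if strongest:
            written["strongest"] = _write_csv(self.strongest, out_dir / "filtered_results.csv")
        return written


def _write_csv(hits: Sequence[HitRecord], path: Path) -> Path:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(TABLE_COLUMNS)
        for hit in hits:
            writer.writerow(hit.to_csv_row())
    return path


def read_results_csv(path: str | Path) -> list[HitRecord]:
    """Load any of the three curated tables back into HitRecord objects.

    The aligned subject string and the program are not stored in the tables,
    so re-loaded hits carry an empty subject and ``program=None``.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise BlastError(f"{path} lacks required columns: {', '.join(missing)}")
    hits = []
    for row in frame.itertuples(index=False):
        raw = {f: getattr(row, f) for f in BLAST_FIELDS}
        kwargs = {
            name: (int(val) if name in _INT_FIELDS
                   else float(val) if name in _FLOAT_FIELDS else val)
            for name, val in raw.items()
        }
        hits.append(
            HitRecord(query_file=row.query_file, database=row.database, raw=raw, **kwargs)
        )
    return hits


def make_databases(
    collection: FastaCollection,
    out_dir: str | Path,
    threads: int = 1,
    sanitize_in_place: bool = False,
) -> list[BlastDatabase]:
    """Build one BLAST database per FASTA file in the collection.

    Database type follows the file extension (``.faa`` → prot, other canonical
    extensions → nucl). Files whose names violate the allowed charset are
    renamed when ``sanitize_in_place`` is set, otherwise the offenders are
    listed in an error. Source stems must be unique across the collection.
    """
    if len(collection) == 0:
        raise BlastError("cannot build databases from an empty collection")
    require_binaries(["makeblastdb"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    offenders = [e.path.name for e in collection if sanitize_filename(e.path.name) != e.path.name]
    if offenders:
        if not sanitize_in_place:
            raise BlastError(
                "file names contain characters incompatible with database creation "
                f"(use --sanitize to rename): {', '.join(offenders)}"
            )
        report = sanitize_collection(collection.paths)
        for entry in collection.entries:
            entry.path = entry.path.with_name(report.mapping[entry.path.name])

    stems = [_stem(e.path) for e in collection]
    dupes = {s for s in stems if stems.count(s) > 1}
    if dupes:
        raise BlastError(f"duplicate source stems across collection: {', '.join(sorted(dupes))}")

    databases = [
        BlastDatabase(
            name=_stem(entry.path),
            db_type="prot" if entry.molecule == "protein" else "nucl",
            prefix=out_dir / _stem(entry.path),
            source=entry.path,
        )
        for entry in collection
    ]

    def build(db: BlastDatabase) -> None:
        cmd = [
            "makeblastdb", "-in", str(db.source), "-dbtype", db.db_type,
            "-out", str(db.prefix), "-title", db.name,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BlastError(f"makeblastdb failed for {db.source.name}: {proc.stderr.strip()}")
        logger.info("built %s database %s from %s", db.db_type, db.name, db.source.name)

    with ThreadPoolExecutor(max_workers=max(1, threads)) as pool:
        list(pool.map(build, databases))
    return databases


def _stem(path: Path) -> str:
    return path.name[: len(path.name) - len("".join(path.suffixes))]


def load_databases(db_dir: str | Path) -> list[BlastDatabase]:
    """Discover formatted databases in a directory by their index files."""
    db_dir = Path(db_dir)
    found: dict[str, BlastDatabase] = {}
    for suffix, db_type in ((".ndb", "nucl"), (".nin", "nucl"), (".pdb", "prot"), (".pin", "prot")):
        for idx in sorted(db_dir.glob(f"*{suffix}")):
            name = idx.name[: -len(suffix)]
            found.setdefault(
                name,
                BlastDatabase(name=name, db_type=db_type, prefix=db_dir / name, source=db_dir / name),
            )
    if not found:
        raise BlastError(f"no BLAST databases found in {db_dir}")
    return [found[name] for name in sorted(found)]


@dataclass
class QueryTask:
    """One unit of parallel work: a single query file against every database."""

    query: Path
    databases: list[BlastDatabase]
    programs: list[str]


def _run_pairing(
    query: Path, db: BlastDatabase, program: str, alignment_dir: Path | None
) -> list[HitRecord]:
    stem = _stem(query)
    cmd = [program, "-query", str(query), "-db", str(db.prefix), "-outfmt", _OUTFMT]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise BlastError(
            f"{program} failed for query {stem!r} vs database {db.name!r}: "
            f"{proc.stderr.strip()}"
        )
    hits = [
        HitRecord.from_tabular_line(line, query_file=stem, database=db.name, program=program)
        for line in proc.stdout.splitlines()
        if line.strip()
    ]
    if alignment_dir is not None:
        aln = subprocess.run(
            [program, "-query", str(query), "-db", str(db.prefix)],
            capture_output=True, text=True,
        )
        (alignment_dir / f"{stem}_vs_{db.name}.txt").write_text(aln.stdout)
    return hits


def run_queries(
    queries: Sequence[str | Path],
    databases: Sequence[BlastDatabase],
    thresholds: ThresholdSet | None = None,
    threads: int = 1,
    nucleotide_query: bool = False,
    write_alignments: bool = False,
    alignment_dir: str | Path | None = None,
) -> ResultsSet:
    """Execute every query×database pairing and curate the results.

    Parallelism assigns one task per query file; within a task the databases
    are searched sequentially. The curated tables are canonically sorted, so
    results are invariant to the thread count. A pairing failure is recorded
    (with the pairing named) without aborting the other pairings.
    """
    if not queries or not databases:
        raise BlastError("run_queries requires at least one query and one database")
    thresholds = thresholds or ThresholdSet()
    programs = {db.name: select_program(db.db_type, nucleotide_query) for db in databases}
    require_binaries(["makeblastdb"] + sorted(set(programs.values())))

    aln_dir: Path | None = None
    if write_alignments:
        aln_dir = Path(alignment_dir) if alignment_dir else Path("alignments")
        aln_dir.mkdir(parents=True, exist_ok=True)

    failures: list[str] = []
    query_paths = [Path(q) for q in queries]

    def run_task(query: Path) -> list[HitRecord]:
        task_hits: list[HitRecord] = []
        for db in databases:
            try:
                task_hits.extend(_run_pairing(query, db, programs[db.name], aln_dir))
            except BlastError as exc:
                logger.error("%s", exc)
                failures.append(str(exc))
        return task_hits

    with ThreadPoolExecutor(max_workers=max(1, threads)) as pool:
        per_task = list(pool.map(run_task, query_paths))

    all_hits = _canonical_sort([h for hits in per_task for h in hits])
    return ResultsSet(all_hits=all_hits, thresholds=thresholds, failures=failures)
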