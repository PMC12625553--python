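"""FASTA input resolution, filename sanitization, splitting, and header de-duplication.

Heterogeneous inputs (plain/gzipped FASTA files, directories, .zip/.tar/.tar.gz/.tgz
archives) are resolved into a flat, validated :class:`FastaCollection`. Archive and
gzip members are staged into a temporary workspace that is removed when the
collection is closed unless ``keep_workspace`` is set.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import random
import re
import shutil
import string
import tarfile
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger("blastkit")

#: Canonical FASTA extensions and the molecule type each implies.
NUCLEOTIDE_EXTENSIONS = (".fasta", ".fna", ".fas", ".fa", ".ffn")
PROTEIN_EXTENSIONS = (".faa",)
CANONICAL_EXTENSIONS = NUCLEOTIDE_EXTENSIONS + PROTEIN_EXTENSIONS

ARCHIVE_SUFFIXES = (".zip", ".tar", ".tar.gz", ".tgz")

_BASE62 = string.digits + string.ascii_uppercase + string.ascii_lowercase


class FastaError(ValueError):
    """Raised for unresolvable, empty, or malformed FASTA inputs."""


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited word of the header, ``description``
    the remainder. ``residues`` are stored uppercase; ``molecule`` is inferred
    from the source file's canonical extension.
    """

    id: str
    description: str
    residues: str
    molecule: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        if re.search(r"\s", self.id):
            raise FastaError(f"record id {self.id!r} contains whitespace")
        self.residues = self.residues.upper()

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(Seq(self.residues), id=self.id, description=self.description)


@dataclass
class FastaEntry:
    """One resolved FASTA file inside a collection."""

    path: Path
    molecule: str
    record_count: int


@dataclass
class FastaCollection:
    """A validated set of FASTA files, possibly staged in a temporary workspace."""

    entries: list[FastaEntry] = field(default_factory=list)
    workspace: Path | None = None
    keep_workspace: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FastaEntry]:
        return iter(self.entries)

    @property
    def paths(self) -> list[Path]:
        return [e.path for e in self.entries]

    def cleanup(self) -> None:
        """Remove the staging workspace unless ``keep_workspace`` is set."""
        if self.workspace is not None and not self.keep_workspace:
            shutil.rmtree(self.workspace, ignore_errors=True)
            self.workspace = None

    def __enter__(self) -> "FastaCollection":
        return self

    def __exit__(self, *exc) -> None:
        self.cleanup()


@dataclass
class SanitizationReport:
    """Mapping of original to sanitized file names plus how renaming was applied."""

    mapping: dict[str, str] = field(default_factory=dict)
    collisions: list[str] = field(default_factory=list)
    mode: str = "in_place"


def detect_molecule_type(name: str | Path) -> str:
    """Map a canonical FASTA extension to ``"nucleotide"`` or ``"protein"``.

    ``.faa`` is amino acid; ``.fasta .fna .fas .fa .ffn`` are nucleotide.
    A trailing ``.gz`` is ignored.
    """
    suffixes = Path(str(name)).suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1].lower() if suffixes else ""
    if ext in PROTEIN_EXTENSIONS:
        return "protein"
    if ext in NUCLEOTIDE_EXTENSIONS:
        return "nucleotide"
    raise FastaError(
        f"unrecognized FASTA extension {ext!r} on {name!r}; "
        f"canonical extensions are {', '.join(CANONICAL_EXTENSIONS)}"
    )


def is_fasta_name(name: str | Path) -> bool:
    try:
        detect_molecule_type(name)
        return True
    except FastaError:
        return False


def sanitize_filename(name: str) -> str:
    """Return ``name`` restricted to letters, digits, ``_`` and ``-`` plus one
    final extension period.

    Every other character is replaced with ``_``; runs of ``_`` collapse to one
    and leading/trailing underscores are stripped from the stem, so the
    function is idempotent. The extension (with optional ``.gz``) is preserved.
    """
    path = Path(name)
    suffixes = path.suffixes
    gz = ""
    if suffixes and suffixes[-1] == ".gz":
        gz = ".gz"
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    stem = name[: len(name) - len(ext) - len(gz)] if (ext or gz) else name
    clean = re.sub(r"[^A-Za-z0-9_-]", "_", stem)
    clean = re.sub(r"_+", "_", clean).strip("_")
    if not clean:
        raise FastaError(f"file name {name!r} sanitizes to an empty stem")
    return clean + ext + gz


def _dedupe_names(names: Iterable[str]) -> tuple[dict[str, str], list[str]]:
    """Sanitize names, suffixing ``_1``, ``_2`` ... before the extension on collision."""
    mapping: dict[str, str] = {}
    collisions: list[str] = []
    seen: set[str] = set()
    for original in names:
        clean = sanitize_filename(original)
        if clean in seen:
            stem = clean[: len(clean) - len("".join(Path(clean).suffixes))]
            ext = clean[len(stem):]
            i = 1
            while f"{stem}_{i}{ext}" in seen:
                i += 1
            clean = f"{stem}_{i}{ext}"
            collisions.append(clean)
        seen.add(clean)
        mapping[original] = clean
    return mapping, collisions


def sanitize_collection(
    paths: Iterable[Path], outdir: Path | None = None
) -> SanitizationReport:
    """Rename files to sanitized names, in place or as copies into ``outdir``."""
    paths = list(paths)
    mapping, collisions = _dedupe_names(p.name for p in paths)
    mode = "in_place" if outdir is None else "copy_to_directory"
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for path in paths:
        new_name = mapping[path.name]
        if outdir is not None:
            shutil.copy2(path, outdir / new_name)
        elif new_name != path.name:
            path.rename(path.with_name(new_name))
    return SanitizationReport(mapping=mapping, collisions=collisions, mode=mode)


def read_fasta(path: str | Path, molecule: str | None = None) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file into :class:`SequenceRecord` objects.

    Wrapped and single-line records are both accepted; a record with an empty
    sequence is rejected.
    """
    path = Path(path)
    if molecule is None:
        molecule = detect_molecule_type(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SequenceRecord] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    description=rec.description[len(rec.id):].strip(),
                    residues=str(rec.seq),
                    molecule=molecule,
                )
            )
    if not records:
        raise FastaError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        SeqIO.write((r.to_seqrecord() for r in records), handle, "fasta")
    return path


def _stage_gzip(src: Path, workspace: Path) -> Path:
    """Decompress a ``.fasta.gz``-style member into the workspace."""
    dest = workspace / src.name[: -len(".gz")]
    with gzip.open(src, "rb") as fin, open(dest, "wb") as fout:
        shutil.copyfileobj(fin, fout)
    return dest


def _extract_archive(archive: Path, workspace: Path) -> None:
    if archive.name.endswith((".tar", ".tar.gz", ".tgz")):
        with tarfile.open(archive) as tf:
            tf.extractall(workspace, filter="data")
    elif archive.suffix == ".zip":
        with zipfile.ZipFile(archive) as zf:
            zf.extractall(workspace)
    else:  # pragma: no cover - guarded by caller
        raise FastaError(f"unsupported archive type: {archive}")


def resolve_inputs(path_spec: str | Path, keep_temp: bool = False) -> FastaCollection:
    """Resolve a file, directory, or archive into a validated FastaCollection.

    Directories and archives are enumerated recursively; gzip members are
    transparently decompressed into a workspace. Non-FASTA files are skipped
    with a logged notice. Every accepted file must parse as FASTA with at least
    one non-empty record.
    """
    path_spec = Path(path_spec)
    if not path_spec.exists():
        raise FastaError(f"input path does not exist: {path_spec}")

    workspace: Path | None = None

    def get_workspace() -> Path:
        nonlocal workspace
        if workspace is None:
            workspace = Path(tempfile.mkdtemp(prefix="blastkit_"))
        return workspace

    candidates: list[Path] = []
    if path_spec.is_dir():
        candidates = sorted(p for p in path_spec.rglob("*") if p.is_file())
    elif path_spec.name.endswith(ARCHIVE_SUFFIXES):
        ws = get_workspace()
        try:
            _extract_archive(path_spec, ws)
        except (tarfile.TarError, zipfile.BadZipFile, OSError) as exc:
            shutil.rmtree(ws, ignore_errors=True)
            raise FastaError(f"unreadable or corrupt archive {path_spec}: {exc}") from exc
        candidates = sorted(p for p in ws.rglob("*") if p.is_file())
    else:
        candidates = [path_spec]

    entries: list[FastaEntry] = []
    for cand in candidates:
        if not is_fasta_name(cand):
            logger.info("skipping non-FASTA file: %s", cand)
            continue
        staged = _stage_gzip(cand, get_workspace()) if cand.suffix == ".gz" else cand
        records = read_fasta(staged)
        entries.append(
            FastaEntry(path=staged, molecule=detect_molecule_type(staged), record_count=len(records))
        )

    if not entries:
        if workspace is not None:
            shutil.rmtree(workspace, ignore_errors=True)
        raise FastaError(f"no FASTA files found under {path_spec}")
    return FastaCollection(entries=entries, workspace=workspace, keep_workspace=keep_temp)


def split_fasta(file: str | Path, batch_size: int = 1, output_dir: str | Path | None = None) -> list[Path]:
    """Partition a multi-FASTA file into batches of ``batch_size`` records.

    Records keep their original order; each output holds ``batch_size`` records
    except possibly the last, so concatenating the outputs round-trips the input.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    file = Path(file)
    records = read_fasta(file)
    output_dir = Path(output_dir) if output_dir is not None else file.parent
    output_dir.mkdir(parents=True, exist_ok=True)

    ext = "".join(s for s in file.suffixes if s != ".gz") or ".fasta"
    stem = file.name[: len(file.name) - len("".join(file.suffixes))]
    outputs: list[Path] = []
    for i in range(0, len(records), batch_size):
        batch = records[i: i + batch_size]
        out = output_dir / f"{stem}_part{i // batch_size + 1}{ext}"
        write_fasta(batch, out)
        outputs.append(out)
    return outputs


def _base62(n: int, length: int) -> str:
    chars = []
    for _ in range(length):
        n, r = divmod(n, 62)
        chars.append(_BASE62[r])
    return "".join(chars)


def deterministic_tag(residues: str, header: str, length: int = 5) -> str:
    """First ``length`` base-62 characters encoded from MD5(residues + header)."""
    digest = hashlib.md5((residues + header).encode()).digest()
    return _base62(int.from_bytes(digest, "big"), length)


def assign_unique_headers(
    collection: FastaCollection,
    deterministic: bool = False,
    seed: int | None = None,
    output_dir: str | Path | None = None,
) -> FastaCollection:
    """Rewrite every record id to ``<id>_<source stem>_<5-char tag>``.

    Random tags draw from a base-62 alphabet (optionally seeded); deterministic
    tags derive from the MD5 digest of (residues + full original header), so
    reruns produce byte-identical headers. Ids are guaranteed pairwise distinct
    across the whole collection.
    """
    rng = random.Random(seed)
    seen: set[str] = set()
    new_entries: list[FastaEntry] = []
    for entry in collection:
        stem = entry.path.name[: len(entry.path.name) - len("".join(entry.path.suffixes))]
        records = read_fasta(entry.path, molecule=entry.molecule)
        renamed: list[SequenceRecord] = []
        for rec in records:
            if deterministic:
                digest = hashlib.md5((rec.residues + rec.header).encode()).digest()
                encoded = _base62(int.from_bytes(digest, "big"), 21)
                tag = encoded[:5]
                extra = 5
                # extend from the same digest encoding until globally unique
                while f"{rec.id}_{stem}_{tag}" in seen and extra < len(encoded):
                    tag = encoded[: 4] + encoded[extra]
                    extra += 1
            else:
                tag = "".join(rng.choice(_BASE62) for _ in range(5))
            new_id = f"{rec.id}_{stem}_{tag}"
            while new_id in seen:
                tag = "".join(rng.choice(_BASE62) for _ in range(5))
                new_id = f"{rec.id}_{stem}_{tag}"
            seen.add(new_id)
            renamed.append(
                SequenceRecord(id=new_id, description=rec.description,
                               residues=rec.residues, molecule=rec.molecule)
            )
        out_path = (Path(output_dir) / entry.path.name) if output_dir else entry.path
        write_fasta(renamed, out_path)
        new_entries.append(FastaEntry(path=out_path, molecule=entry.molecule,
                                      record_count=len(renamed)))
    return FastaCollection(entries=new_entries, workspace=collection.workspace,
                           keep_workspace=collection.keep_workspace)
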