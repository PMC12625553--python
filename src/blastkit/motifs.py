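"""Wildcard amino-acid motif mining over alignment hits.

A motif is written in one-letter amino-acid code with ``X`` as a wildcard
(e.g. ``WXWXIP``); appending ``{stem}`` binds the pattern to hits from the
query file with that stem (e.g. ``RVXXXQ{AT}``). Scanning runs over the
de-gapped subject residues of every hit regardless of inclusion thresholds,
reports all (including overlapping) occurrences, and is case-insensitive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .blast import HitRecord
from .fasta_io import SequenceRecord, write_fasta

logger = logging.getLogger("blastkit")

STANDARD_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_TOKEN_RE = re.compile(r"^([A-Za-z]+)(?:\{([^{}]+)\})?$")


class MotifError(ValueError):
    """Raised for malformed motif tokens or unusable scan targets."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed wildcard motif, optionally bound to one query-file stem.

    ``positions`` holds fixed uppercase residue letters with ``None`` at
    wildcard positions. ``X`` always wildcards; a literal fixed X is
    unsupported.
    """

    raw: str
    positions: tuple[str | None, ...]
    binding: str | None = None

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def motif(self) -> str:
        return "".join("X" if p is None else p for p in self.positions)

    def matches_window(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            p is None or p == c for p, c in zip(self.positions, window)
        )

    def to_regex(self) -> re.Pattern:
        body = "".join("[A-Z]" if p is None else re.escape(p) for p in self.positions)
        return re.compile(f"(?=({body}))")


@dataclass
class MotifMatch:
    """One occurrence of a pattern within a hit's de-gapped subject residues.

    ``start`` is 1-based within the de-gapped subject alignment string.
    """

    pattern: MotifPattern
    hit: HitRecord
    start: int
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


def parse_motif_token(token: str) -> MotifPattern:
    m = _TOKEN_RE.match(token)
    if m is None:
        if "{" in token or "}" in token:
            raise MotifError(f"malformed brace binding in motif token {token!r}")
        raise MotifError(
            f"illegal character in motif token {token!r}; "
            "motifs use one-letter amino-acid codes with X as wildcard"
        )
    body, binding = m.group(1).upper(), m.group(2)
    positions: list[str | None] = []
    for ch in body:
        if ch == "X":
            positions.append(None)
        elif ch in STANDARD_AMINO_ACIDS:
            positions.append(ch)
        else:
            raise MotifError(
                f"{ch!r} in motif {token!r} is not a standard one-letter amino-acid code"
            )
    return MotifPattern(raw=token, positions=tuple(positions), binding=binding)


def parse_motif_spec(tokens: Sequence[str]) -> list[MotifPattern]:
    """Parse the ``--motif`` token list into patterns."""
    if not tokens:
        raise MotifError("at least one motif token is required")
    return [parse_motif_token(t) for t in tokens]


def scan_sequence(residues: str, pattern: MotifPattern, hit: HitRecord | None = None) -> list[MotifMatch]:
    """Find every occurrence of ``pattern`` in ``residues``, overlaps included.

    Matches are returned in ascending start order with 1-based coordinates.
    """
    residues = residues.upper()
    return [
        MotifMatch(pattern=pattern, hit=hit, start=m.start() + 1, matched=m.group(1))
        for m in pattern.to_regex().finditer(residues)
    ]


def plan_scans(
    patterns: Sequence[MotifPattern], hits: Sequence[HitRecord]
) -> list[tuple[MotifPattern, HitRecord]]:
    """Pair patterns with the hits they should scan.

    Unbound patterns pair with every hit; a ``{stem}``-bound pattern pairs only
    with hits whose query-file stem matches. All hits participate regardless of
    threshold status, but nucleotide-subject (blastn) hits are refused: motifs
    are amino-acid patterns and apply to blastp/tblastn subject residues.
    """
    if any(h.program == "blastn" for h in hits):
        raise MotifError(
            "motif scanning requires amino-acid subject residues; "
            "blastn (nucleotide) results cannot be scanned"
        )
    stems = {h.query_file for h in hits}
    pairs: list[tuple[MotifPattern, HitRecord]] = []
    for pattern in patterns:
        if pattern.binding is not None and pattern.binding not in stems:
            logger.warning(
                "motif %s is bound to query stem %r which matches no hit; skipping",
                pattern.raw, pattern.binding,
            )
            continue
        for hit in hits:
            if pattern.binding is None or hit.query_file == pattern.binding:
                pairs.append((pattern, hit))
    return pairs


def scan_hits(
    patterns: Sequence[MotifPattern], hits: Sequence[HitRecord]
) -> list[MotifMatch]:
    """Scan every planned (pattern, hit) pair over de-gapped subject residues."""
    matches: list[MotifMatch] = []
    for pattern, hit in plan_scans(patterns, hits):
        matches.extend(scan_sequence(hit.degapped_subject, pattern, hit=hit))
    return matches


def match_table(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    columns = ["motif", "database", "sseqid", "qseqid", "start", "end", "matched"]
    rows = [
        {
            "motif": m.pattern.raw,
            "database": m.hit.database if m.hit else "",
            "sseqid": m.hit.sseqid if m.hit else "",
            "qseqid": m.hit.qseqid if m.hit else "",
            "start": m.start,
            "end": m.end,
            "matched": m.matched,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=columns)


def export_motif_fasta(
    matches: Sequence[MotifMatch], out_dir: str | Path, motif_only: bool = False
) -> list[Path]:
    """Write one FASTA per distinct pattern that has at least one match.

    Records carry the full de-gapped subject residues of the hit by default, or
    just the matched substring with ``motif_only``. Headers identify database,
    subject, and 1-based match coordinates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_pattern: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_pattern.setdefault(m.pattern.motif, []).append(m)

    outputs: list[Path] = []
    for motif, group in by_pattern.items():
        records = []
        for m in group:
            db = m.hit.database if m.hit else "unknown"
            sid = m.hit.sseqid if m.hit else "unknown"
            residues = m.matched if motif_only else (m.hit.degapped_subject if m.hit else m.matched)
            records.append(
                SequenceRecord(
                    id=f"{db}_{sid}_{m.start}-{m.end}",
                    description=f"motif={motif}",
                    residues=residues,
                    molecule="protein",
                )
            )
        path = out_dir / f"motif_{motif}.faa"
        write_fasta(records, path)
        outputs.append(path)
    return outputs
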