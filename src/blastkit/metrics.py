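"""Per-file assembly statistics: size, GC%, N count, N50/N90, L50/L90, length summary."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fasta_io import SequenceRecord, read_fasta, resolve_inputs


@dataclass
class AssemblyMetrics:
    """Assembly statistics for one FASTA file.

    ``lengths`` is sorted descending; GC% uses all residues (ambiguity codes
    and N included) as the denominator, with N counted separately.
    """

    genome_size: int
    contig_count: int
    gc_percent: float
    n_count: int
    n50: int
    n90: int
    l50: int
    l90: int
    longest: int
    shortest: int
    lengths: list[int]
    length_distribution: dict[str, float]

    def to_row(self) -> dict:
        row = {
            "genome_size": self.genome_size,
            "contig_count": self.contig_count,
            "gc_percent": round(self.gc_percent, 2),
            "n_count": self.n_count,
            "n50": self.n50,
            "n90": self.n90,
            "l50": self.l50,
            "l90": self.l90,
            "longest_contig": self.longest,
            "shortest_contig": self.shortest,
        }
        row.update({f"length_{k}": v for k, v in self.length_distribution.items()})
        row["contig_lengths"] = "|".join(str(n) for n in self.lengths)
        return row


def n_statistic(lengths: Sequence[int], fraction: float) -> tuple[int, int]:
    """Return (N, L) at ``fraction`` of the total assembly length.

    With lengths sorted descending, N is the contig length at which the running
    sum first reaches ``fraction * total``; L is the number of contigs consumed
    to get there. ``fraction=0.5`` gives (N50, L50), ``0.9`` gives (N90, L90).
    """
    if not lengths:
        raise ValueError("n_statistic requires a non-empty length list")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ordered = sorted(lengths, reverse=True)
    threshold = fraction * sum(ordered)
    running = 0
    for i, n in enumerate(ordered, start=1):
        running += n
        if running >= threshold:
            return n, i
    raise AssertionError("unreachable")  # pragma: no cover


def compute_metrics(records: Iterable[SequenceRecord]) -> AssemblyMetrics:
    """Compute all assembly statistics for one set of contigs.

    GC and N counting are case-insensitive (records store residues uppercase).
    """
    records = list(records)
    if not records:
        raise ValueError("compute_metrics requires at least one record")
    lengths = sorted((len(r.residues) for r in records), reverse=True)
    total = sum(lengths)
    gc = sum(r.residues.count("G") + r.residues.count("C") for r in records)
    n_count = sum(r.residues.count("N") for r in records)
    n50, l50 = n_statistic(lengths, 0.5)
    n90, l90 = n_statistic(lengths, 0.9)
    arr = np.array(lengths, dtype=float)
    distribution = {
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "q3": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
    }
    return AssemblyMetrics(
        genome_size=total,
        contig_count=len(lengths),
        gc_percent=100.0 * gc / total,
        n_count=n_count,
        n50=n50,
        n90=n90,
        l50=l50,
        l90=l90,
        longest=lengths[0],
        shortest=lengths[-1],
        lengths=lengths,
        length_distribution=distribution,
    )


def metrics_table(path_spec: str | Path, keep_temp: bool = False) -> pd.DataFrame:
    """One metrics row per FASTA file under ``path_spec``."""
    rows = []
    with resolve_inputs(path_spec, keep_temp=keep_temp) as collection:
        for entry in collection:
            m = compute_metrics(read_fasta(entry.path, molecule=entry.molecule))
            rows.append({"file": entry.path.name, **m.to_row()})
    return pd.DataFrame(rows)
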