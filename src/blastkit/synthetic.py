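"""Synthetic genome/query generation for validation and examples.

Builds small random genomes with known protein-coding genes planted at known
coordinates (optionally reverse-complemented), plus the matching amino-acid
query files. A query planted verbatim must come back from the search pipeline
as a 100% identity / 100% coverage self-hit, and extracting its coordinates
must recover the planted sequence exactly — which is what the validation
suite checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .extraction import reverse_complement
from .fasta_io import SequenceRecord, write_fasta

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One fixed codon per amino acid, so protein→DNA encoding is deterministic
#: and translates back exactly (standard genetic code).
CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def encode_protein(protein: str) -> str:
    """Back-translate a protein with the fixed codon table."""
    return "".join(CODON[aa] for aa in protein)


@dataclass
class Placement:
    """Where one gene was planted: 1-based inclusive plus-strand interval."""

    gene: str
    genome: str
    contig: str
    start: int
    end: int
    strand: str  # "+" | "-"


@dataclass
class PlantedDataset:
    """A set of synthetic genomes with known planted genes and their queries."""

    genome_dir: Path
    query_dir: Path
    genomes: list[str]
    proteins: dict[str, str]
    gene_dna: dict[str, str]
    placements: list[Placement] = field(default_factory=list)

    def placements_for(self, gene: str) -> list[Placement]:
        return [p for p in self.placements if p.gene == gene]


def build_planted_dataset(
    root: str | Path,
    seed: int = 0,
    n_genomes: int = 4,
    n_genes: int = 3,
    genome_length: int = 12_000,
    protein_length: int = 80,
    reverse_gene_index: int | None = 2,
    skip: set[tuple[int, int]] | None = None,
) -> PlantedDataset:
    """Create ``n_genomes`` two-contig genomes, each carrying every gene.

    Gene ``reverse_gene_index`` is planted reverse-complemented. ``skip`` holds
    (gene index, genome index) pairs to leave out, producing empty
    query×genome pairings. Genes are spaced on the first contig with at least
    500 bp of random flank on either side.
    """
    root = Path(root)
    rng = random.Random(seed)
    skip = skip or set()

    genome_dir = root / "genomes"
    query_dir = root / "queries"
    genome_dir.mkdir(parents=True, exist_ok=True)
    query_dir.mkdir(parents=True, exist_ok=True)

    proteins = {f"gene{i + 1}": random_protein(rng, protein_length) for i in range(n_genes)}
    gene_dna = {name: encode_protein(p) for name, p in proteins.items()}

    for name, protein in proteins.items():
        write_fasta(
            [SequenceRecord(id=name, description="planted query", residues=protein,
                            molecule="protein")],
            query_dir / f"{name}.faa",
        )

    dataset = PlantedDataset(
        genome_dir=genome_dir, query_dir=query_dir,
        genomes=[f"genome{i + 1}" for i in range(n_genomes)],
        proteins=proteins, gene_dna=gene_dna,
    )

    gene_len = protein_length * 3
    spacing = 500
    for gi, genome in enumerate(dataset.genomes):
        contig1_parts: list[str] = []
        pos = 1
        for idx, (name, dna) in enumerate(gene_dna.items()):
            flank = random_dna(rng, spacing)
            contig1_parts.append(flank)
            pos += spacing
            if (idx, gi) in skip:
                continue
            planted = dna
            strand = "+"
            if reverse_gene_index is not None and idx == reverse_gene_index:
                planted = reverse_complement(dna)
                strand = "-"
            contig1_parts.append(planted)
            dataset.placements.append(
                Placement(gene=name, genome=genome, contig=f"{genome}_contig1",
                          start=pos, end=pos + gene_len - 1, strand=strand)
            )
            pos += gene_len
        contig1_parts.append(random_dna(rng, spacing))
        contig1 = "".join(contig1_parts)

        filler = max(genome_length - len(contig1), 1_000)
        contig2 = random_dna(rng, filler)
        write_fasta(
            [
                SequenceRecord(id=f"{genome}_contig1", description="synthetic",
                               residues=contig1),
                SequenceRecord(id=f"{genome}_contig2", description="synthetic",
                               residues=contig2),
            ],
            genome_dir / f"{genome}.fna",
        )
    return dataset
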