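"""Shared fixtures: synthetic planted-gene datasets and a cached pipeline run.

The BLAST-backed pipeline fixture is session-scoped so the external searches
run once and are shared by the pipeline, extraction, visualization, and
acceptance tests.
"""

from __future__ import annotations

import pytest

from blastkit import blast, fasta_io, synthetic


def make_hit(**overrides) -> blast.HitRecord:
    """A plausible filtered-by-default hit; override fields per test."""
    defaults = dict(
        qseqid="q1", sseqid="s1", pident=100.0, evalue=1e-50, length=100,
        mismatch=0, gapopen=0, qstart=1, qend=100, sstart=1, send=100,
        bitscore=200.0, qlen=100, sframe=1, subject_residues="M" * 100,
        query_file="q1", database="db1", program="tblastn",
    )
    defaults.update(overrides)
    return blast.HitRecord(**defaults)


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """4 genomes × 3 planted genes (gene3 reverse-complemented); gene1 is
    absent from genome4 so one query×database pairing stays empty."""
    root = tmp_path_factory.mktemp("planted")
    return synthetic.build_planted_dataset(
        root, seed=11, n_genomes=4, n_genes=3, reverse_gene_index=2,
        skip={(0, 3)},
    )


@pytest.fixture(scope="session")
def pipeline(planted_dataset, tmp_path_factory):
    """makedb + query over the planted dataset, tables written once."""
    work = tmp_path_factory.mktemp("pipeline")
    with fasta_io.resolve_inputs(planted_dataset.genome_dir) as collection:
        dbs = blast.make_databases(collection, work / "db", threads=2)
    queries = sorted(planted_dataset.query_dir.glob("*.faa"))
    results = blast.run_queries(queries, dbs, threads=2)
    out = work / "results"
    written = results.write_tables(out, strongest=True)
    return {
        "dataset": planted_dataset,
        "databases": dbs,
        "results": results,
        "out_dir": out,
        "tables": written,
    }
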