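# blastkit

Population-scale comparative genomics with BLAST+ usually means writing
throwaway shell loops: format every assembly into a database, pick the right
search program per pairing, run hundreds of query×database jobs, then stitch
and filter a pile of per-pairing output files. `blastkit` automates that
workflow for microbial genome mining — pangenome screens, biosynthetic gene
cluster (BGC) discovery, resistance-gene surveys — and adds the curation
steps those projects need around the searches themselves: wildcard
amino-acid motif mining, aligned-region and contig extraction with genomic
context, assembly metrics, metadata harvesting, and figure generation.

## What it does

* **makedb** — one BLAST database per FASTA file, from files, directories,
  gzip members, or `.zip`/`.tar`/`.tar.gz`/`.tgz` archives. Database type is
  detected from the extension (`.faa` → protein; `.fasta .fna .fas .fa .ffn`
  → nucleotide). File names are checked against the BLAST-safe character set
  (letters, digits, `_`, `-`, one extension period) and can be sanitized in
  place or as copies.
* **query** — every query against every database, with the program chosen
  per pairing: nucleotide database + amino-acid query → `tblastn`, protein
  database + amino-acid query → `blastp`, `--nucleotide-query` → `blastn`.
  Parallelism assigns one query file per task; the curated tables are
  canonically sorted and therefore identical for any `--threads` value.
  Three CSV tables are produced: `all_results.csv` (every hit),
  `all_filtered_results.csv` (hits with pident ≥ 90 %, query coverage ≥ 75 %
  and E-value ≤ 1e-5 by default, all inclusive; query coverage is
  100·(qend − qstart + 1)/qlen), and with `--report-strongest-matches`
  `filtered_results.csv` — the single best hit per query×database pairing
  (maximal bitscore, ties by minimal E-value, maximal pident, then sseqid).
* **motif mining** (`--motif`) — patterns in one-letter amino-acid code with
  `X` as a wildcard (`RVXXXQ`), optionally bound to one query file
  (`RVXXXQ{AT}`). Scanning runs over the de-gapped subject residues of *all*
  hits regardless of thresholds, reports every (including overlapping)
  occurrence, and can export matches as FASTA (`--motif-fasta-out`, with
  `--motif-only` for just the matched substring).
* **extract / extract-contig** — pull the aligned subject interval (1-based,
  minus strand encoded by sstart > send and returned reverse-complemented)
  with optional `--up`/`--down` flanking padding applied on the hit's 5′/3′
  side, or the entire contig behind a hit.
* **utilities** — `fasta-metrics` (genome size, GC %, N count, N50/N90,
  L50/L90 by the cumulative-prefix rule, contig length distribution),
  `split-fasta`, `sanitize`, `unique-header` (collision-free ids
  `<id>_<file stem>_<5-char tag>`, deterministic from an MD5 digest with
  `--deterministic`), and `search` (GenBank/JSON metadata to CSV/TSV/JSON,
  missing values as `not_specified`).
* **visualization** (`--visualize [--pdf]`) — a query×database percent-identity
  heatmap (maximum pident per pairing, empty pairings in a reserved color)
  and one sequence logo per motif, letter heights scaled by frequency ×
  information content R = log2 20 − H bits. Rasters are written at 300 dpi.

## Worked example

Generate two small synthetic genomes with two planted genes (one inserted
reverse-complemented), then search and mine them:

```python
from blastkit import synthetic
synthetic.build_planted_dataset(".", seed=4, n_genomes=2, n_genes=2,
                                reverse_gene_index=1)
```

```
$ blastkit makedb --input genomes --out db
built 2 database(s) in db

$ blastkit query --databases db --queries queries --output results \
    --report-strongest-matches --visualize --motif "PVXCXT{gene1}"
12 hit(s), 4 passing thresholds; tables in results
```

`filtered_results.csv` holds the strongest match per pairing; both planted
queries come back as full-length perfect hits (pident 100, qcov 100.00), and
gene1 lands on the plus strand of each genome's first contig at 501–740:

```
qseqid,sseqid,pident,evalue,length,mismatch,gapopen,qstart,qend,sstart,send,bitscore,qlen,sframe,qcov,query_file,database
gene1,genome1_contig1,100.000,2.04e-56,80,0,0,1,80,501,740,173,80,3,100.00,gene1,genome1
gene1,genome2_contig1,100.000,7.70e-56,80,0,0,1,80,501,740,172,80,3,100.00,gene1,genome2
```

The bound motif `PVXCXT{gene1}` is scanned only in gene1's hits and reports
each occurrence with 1-based coordinates in the de-gapped subject:

```
motif,database,sseqid,qseqid,start,end,matched
PVXCXT{gene1},genome1,genome1_contig1,gene1,10,15,PVLCIT
PVXCXT{gene1},genome2,genome2_contig1,gene1,10,15,PVLCIT
```

`results/` also gains `identity_heatmap.png` and `logo_PVXCXT.png` (300 dpi).
Assembly statistics for one genome:

```
$ blastkit fasta-metrics --input genomes/genome1.fna
       file  genome_size  contig_count  gc_percent  n_count   n50   n90  l50  l90 ... contig_lengths
genome1.fna        12000             2       49.99        0 10020  1980    1    2 ...     10020|1980
```

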