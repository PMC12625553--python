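# Methods

## Scope and model of operation

`blastkit` is an orchestration layer, not an aligner: all alignment is
delegated to the NCBI BLAST+ binaries (`makeblastdb`, `blastn`, `blastp`,
`tblastn`) through subprocess calls with explicit argument lists. The
package's own contribution is everything around the searches — input
resolution, program dispatch, parallel execution, table curation, the
wildcard motif DSL, coordinate-safe extraction, and the derived statistics
and figures. Remote BLAST, profile/HMM search and re-implementation of the
alignment algorithm are out of scope; degenerate or gapped motif families
are better served by HMM tools than by the exact wildcard scanner here.

## Input handling

Inputs may be single FASTA files (optionally gzipped), directories, or
`.zip`/`.tar`/`.tar.gz`/`.tgz` archives. Archives and gzip members are
staged into a temporary workspace that is deleted at the end of the run
unless `--keep-temp-files` is given. Non-FASTA files inside directories and
archives are skipped with a logged notice rather than failing the run, so a
stray README in a genome folder cannot abort a batch. A file must parse as
FASTA with at least one non-empty record to be accepted; wrapped and
single-line records are both fine.

Molecule type comes from the canonical extension — `.faa` is amino acid,
`.fasta .fna .fas .fa .ffn` are nucleotide — because database type and
program dispatch must be decided before any sequence content is read.

### Filename sanitization

BLAST+ tooling misbehaves on spaces, parentheses and extra periods in file
names. The allowed character set is letters, digits, underscore, hyphen and
exactly one final extension period; every other character becomes `_`, runs
of `_` collapse, and leading/trailing underscores are stripped from the
stem, which makes the transform idempotent. Post-sanitization collisions get
`_1`, `_2`, … suffixes before the extension, in input order, so batch runs
are deterministic.

### Unique headers

CDS-prediction pipelines emit duplicate ids ("hypothetical protein")
that break downstream bookkeeping. `unique-header` rewrites every id to
`<id>_<source stem>_<tag>` with a 5-character base-62 tag. In deterministic
mode the tag is the first five base-62 characters encoded from the MD5
digest of (residues + full original header), so reruns are byte-identical
and records differing in either sequence or header get different tags; in
random mode the tag draws from a seedable RNG. Both modes fall back to
re-drawing (or extending along the digest encoding) until the id is globally
unique across the collection, so even thousands of fully identical records
end up distinct.

## Search orchestration

### Dispatch and thresholds

Program choice per query×database pairing: nucleotide database +
amino-acid query → `tblastn`; protein database + amino-acid query →
`blastp`; nucleotide database + `--nucleotide-query` → `blastn`. A
nucleotide query against a protein database has no supported program and is
an error.

Default inclusion thresholds are 90 % identity, 75 % query coverage and an
E-value of 1e-5. Comparisons are inclusive at the boundary (≥, ≥, ≤): a hit
at exactly the printed defaults passes. Query coverage is computed from the
query span, `100·(qend − qstart + 1)/qlen`, rounded to two decimals; the
alignment-length alternative (counting gaps) was rejected because it can
exceed 100 % and makes the 75 % default harder to interpret.

### Execution and determinism

Parallelism follows the one-query-file-per-task rule: tasks run in a thread
pool up to `--threads`, and within a task the databases are searched
sequentially. Thread workers are sufficient because the work happens in
external subprocesses. Hits are collected via a custom tabular format that
appends `qlen`, `sframe` and the aligned subject string (`sseq`) to the
standard 12 fields; the subject string stays in memory for the motif engine
and is not written to the tables. Output tables are canonically sorted —
(query_file, database, E-value ascending, bitscore descending, sseqid,
sstart) — which makes them invariant to the thread count. Numeric fields
are carried verbatim from the search tool's text output (no re-rounding);
only the computed `qcov` column is formatted, with two decimals.

A failed pairing is logged with the pairing named and recorded in the
results object without aborting the other pairings; the CLI exits 3 when
any pairing failed but partial tables were written.

### Strongest match

`--report-strongest-matches` keeps at most one hit per (query_file,
database) pairing: maximal bitscore, ties broken by minimal E-value, then
maximal percent identity, then lexicographically smallest sseqid. The full
tie-break chain exists only to make the output deterministic; in practice
bitscore and E-value decide.

## Motif engine

Patterns use the 20 standard one-letter amino-acid codes with `X` as a
wildcard matching any letter; `{stem}` binds a pattern to hits from one
query file. Scanning happens on the de-gapped subject residues (gap
characters stripped) so an alignment gap cannot split a genuine motif, and
over *all* hits regardless of thresholds, because motif carriers in
heterogeneous gene families often sit below strict identity cutoffs. All
occurrences are reported, including overlapping ones — iterative motifs
such as paired copper-binding HXXHC sites are exactly the case where
leftmost-non-overlapping semantics would lose information. Matching is
case-insensitive on both sides. Match coordinates are 1-based within the
de-gapped subject alignment, not the full subject sequence. A literal fixed
X cannot be expressed (X always wildcards) — a documented limitation.
Nucleotide-subject (blastn) results are refused: the alphabet overlap would
make any apparent match meaningless.

## Extraction

Coordinates follow BLAST conventions: 1-based inclusive, minus-strand
subject hits encoded by sstart > send (tblastn/blastn). Internally the
arithmetic converts to 0-based half-open and back. Padding is oriented —
`--up` extends the 5′ side of the hit *in hit orientation* — and
minus-strand output is reverse-complemented so extracted genes read
forward; this is the convention a user inspecting genomic context of a hit
expects. Intervals are clamped to the contig silently, but the output
header records both the requested and the applied interval so clamping is
visible. Region mode writes one multi-FASTA per run; contig mode writes one
per database and emits each contig once no matter how many hits landed on
it. Any of the three results tables can drive extraction, since all share
the same schema.

## Assembly metrics

N50/L50 (and N90/L90) use the standard cumulative rule: with contig lengths
sorted descending, N is the length at which the running sum first reaches
the fraction of the total, L the number of contigs consumed. GC % uses all
residues as denominator, ambiguity codes and N included, with the N count
reported separately — mixing the two conventions silently inflates GC on
draft assemblies. The contig length distribution is summarized as
min/Q1/median/mean/Q3/max, and the per-contig length list is emitted
descending-sorted with `|` separators. Counting is case-insensitive
(records are upper-cased on parse).

## Metadata harvesting

File type is sniffed from content (a LOCUS line vs a JSON object), not the
extension. GenBank mapping: accession ← VERSION (falling back to the record
id), organism ← SOURCE/ORGANISM, host and isolation_source from the source
feature qualifiers, and collection_region ← `/geo_loc_name` with
`/country` as fallback (INSDC renamed the qualifier; both appear in the
wild). The JSON path targets NCBI assembly data reports: leaves are
flattened, biosample attribute lists (`{"name": …, "value": …}`) are lifted
to key/value pairs, and a small synonym table maps report keys to the five
default fields. `--all` adds every additional qualifier observed across the
batch, union-ordered by first appearance. Missing values are always the
literal `not_specified`; no output cell is ever empty, which keeps
downstream joins honest. CSV and TSV emissions are cell-for-cell identical.

## Visualization

The heatmap shows one cell per query×database pairing, colored by the
maximum percent identity among that pairing's *filtered* hits — maximum,
because multiple HSPs against one genome usually reflect one locus plus
fragments, and the best fragment is the signal. Pairings with no filtered
hit are rendered in a reserved grey distinct from the 0–100 colormap.
Heatmaps require at least two databases; below that the figure is skipped.

Sequence logos are drawn directly with matplotlib glyph paths: per-position
residue frequencies come from the matched strings, letter heights are
frequency × information content R_i = log2 20 − H_i (Shannon entropy in
bits over the 20-letter alphabet), with no small-sample correction — at the
match counts motif mining produces, a correction would mostly hide the
conservation signal the logo exists to show. An all-identical column
reaches exactly log2 20 ≈ 4.32 bits; wildcard-heavy columns show
correspondingly low information. All rasters are written at 300 dpi; PDF
output replaces PNG when `--pdf` is set. One logo is produced per pattern
that returned at least one match.

## CLI shell

All subcommands hang off one entry point. Implementation modules are
imported lazily inside each command, so a broken component (say, a plotting
stack problem) cannot take down unrelated subcommands; `module-health`
probes every subcommand's module for importability and checks the four
external binaries on PATH. Exit codes: 0 success, 1 usage error, 2
environment error (missing binaries), 3 partial failure. Each pipeline run
appends a timestamped log naming the inputs, parameters and outputs next to
its results. Configuration is flags-only with defaults equal to the shipped
thresholds; heatmap rows are keyed by qseqid (with the recommended
one-sequence-per-query-file layout this coincides with the query file stem).

## Synthetic data and what the tests show

The validation datasets are built by `blastkit.synthetic`: random-composition
genomes of ~12 kb in two contigs, with random 80-residue proteins
back-translated through a fixed one-codon-per-amino-acid table and planted
at known coordinates with ≥500 bp random flanks; one gene is inserted
reverse-complemented, and selected query×genome pairings can be left empty.
Problem sizes (4–5 genomes, 3 queries, 80-residue genes) keep a full
makedb→query→extract→visualize cycle in the low seconds while still
exercising both strands, multi-contig assemblies and empty pairings.

Because planted queries are exact back-translations, self-hits must come
back at 100 % identity and coverage, zero-padding extraction must return
the planted sequence byte-for-byte, and padded extraction must return the
known flanks — these are closed-form expectations, not tolerances. What the
synthetic data does *not* emulate: realistic codon usage and GC skew, repeat
content, fragmented or contaminated assemblies, and divergent homologs near
the threshold boundary. Passing tests therefore validate the orchestration,
curation, coordinate arithmetic and determinism contracts, not BLAST's
sensitivity on real data — which is BLAST's own concern. The motif engine
is additionally validated against the documented acyltransferase,
ketosynthase and ketoreductase domain-motif contexts of the erythromycin
PKS modules, and both the scanner and the N/L statistics are cross-checked
against independent brute-force oracles on 1,000 random cases each.

## Numerical and degenerate-input choices

* Threshold and coverage comparisons are inclusive; coverage is rounded to
  two decimals before comparison so what is printed is what is filtered.
* Ties in contig length (N/L statistics) are broken by sort order and
  cannot affect the result.
* Empty results produce header-only tables, zero motif matches produce no
  FASTA/logo file, and an empty heatmap axis skips the figure.
* An archive with no FASTA members, an empty FASTA record, a batch with
  duplicate database stems, and a nucleotide query against a protein
  database are all hard errors; unreadable metadata files and unmatched
  motif bindings are warnings.
* The acceptance script derives all randomness from `--seed` and regenerates
  its dataset per run; nothing is cached between invocations.
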