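"""FASTA input resolution, sanitization, splitting, and header de-duplication."""

from __future__ import annotations

import gzip
import shutil
import tarfile
import zipfile

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastkit import fasta_io
from blastkit.fasta_io import (
    FastaError,
    SequenceRecord,
    assign_unique_headers,
    detect_molecule_type,
    read_fasta,
    resolve_inputs,
    sanitize_filename,
    split_fasta,
    write_fasta,
)


def _write(path, records):
    write_fasta(records, path)
    return path


def _records(n, prefix="rec", length=30):
    return [
        SequenceRecord(id=f"{prefix}{i}", description=f"desc {i}",
                       residues="ACGT" * (length // 4) + "AC"[: length % 4])
        for i in range(n)
    ]


class TestDetectMoleculeType:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("q.faa", "protein"),
            ("g.ffn", "nucleotide"),
            ("g.fasta", "nucleotide"),
            ("g.fna", "nucleotide"),
            ("g.fas", "nucleotide"),
            ("g.fa", "nucleotide"),
            ("g.fna.gz", "nucleotide"),
            ("g.faa.gz", "protein"),
        ],
    )
    def test_canonical_extensions(self, name, expected):
        assert detect_molecule_type(name) == expected

    def test_unrecognized_extension_lists_canonical_ones(self):
        with pytest.raises(FastaError, match=r"\.fasta"):
            detect_molecule_type("g.txt")


class TestSanitizeFilename:
    @pytest.mark.parametrize(
        "raw,clean",
        [
            ("E. coli (K-12).fna", "E_coli_K-12.fna"),
            ("genome1.fna", "genome1.fna"),
            ("a b  c.fasta", "a_b_c.fasta"),
            ("strain#7 [v2].faa", "strain_7_v2.faa"),
            ("x.y.z.fna.gz", "x_y_z.fna.gz"),
        ],
    )
    def test_charset_rule(self, raw, clean):
        assert sanitize_filename(raw) == clean

    def test_empty_stem_rejected(self):
        with pytest.raises(FastaError):
            sanitize_filename("(((.fna")

    @settings(max_examples=200, deadline=None)
    @given(st.text(min_size=1, max_size=30).filter(lambda s: "/" not in s))
    def test_idempotent(self, stem):
        try:
            once = sanitize_filename(stem + ".fna")
        except FastaError:
            return
        assert sanitize_filename(once) == once

    def test_collision_suffixes(self, tmp_path):
        for name in ("strainA!.fna", "strainA?.fna"):
            _write(tmp_path / name, _records(1))
        report = fasta_io.sanitize_collection(sorted(tmp_path.iterdir()))
        assert sorted(report.mapping.values()) == ["strainA.fna", "strainA_1.fna"]
        assert report.collisions == ["strainA_1.fna"]


class TestResolveInputs:
    def test_directory_skips_non_fasta(self, tmp_path):
        for i in range(3):
            _write(tmp_path / f"g{i}.fna", _records(2))
        (tmp_path / "notes.txt").write_text("not fasta")
        with resolve_inputs(tmp_path) as coll:
            assert len(coll) == 3

    def test_archive_staged_in_removable_workspace(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        for i in range(2):
            _write(src / f"g{i}.fasta", _records(2))
        archive = tmp_path / "bundle.tar.gz"
        with tarfile.open(archive, "w:gz") as tf:
            tf.add(src, arcname="bundle")
        coll = resolve_inputs(archive)
        assert len(coll) == 2
        workspace = coll.workspace
        assert workspace is not None and workspace.exists()
        coll.cleanup()
        assert not workspace.exists()

    def test_zip_matches_unpacked_directory(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        for i in range(3):
            _write(src / f"g{i}.fna", _records(i + 1, prefix=f"g{i}_"))
        archive = tmp_path / "bundle.zip"
        with zipfile.ZipFile(archive, "w") as zf:
            for p in sorted(src.iterdir()):
                zf.write(p, arcname=p.name)

        def record_multiset(collection):
            return sorted(
                (r.id, r.residues)
                for e in collection
                for r in read_fasta(e.path, molecule=e.molecule)
            )

        with resolve_inputs(src) as direct, resolve_inputs(archive) as unpacked:
            assert record_multiset(direct) == record_multiset(unpacked)

    def test_gzip_member_decompresses_identically(self, tmp_path):
        plain = _write(tmp_path / "genome.fna", _records(3))
        gz = tmp_path / "z" / "genome.fna.gz"
        gz.parent.mkdir()
        with open(plain, "rb") as fin, gzip.open(gz, "wb") as fout:
            shutil.copyfileobj(fin, fout)
        with resolve_inputs(gz) as coll:
            assert coll.entries[0].path.read_bytes() == plain.read_bytes()

    def test_errors(self, tmp_path):
        with pytest.raises(FastaError):
            resolve_inputs(tmp_path / "ghost")
        empty = tmp_path / "empty.zip"
        with zipfile.ZipFile(empty, "w"):
            pass
        with pytest.raises(FastaError):
            resolve_inputs(empty)
        corrupt = tmp_path / "bad.tar.gz"
        corrupt.write_bytes(b"not an archive")
        with pytest.raises(FastaError):
            resolve_inputs(corrupt)


class TestRoundTrip:
    @settings(max_examples=50, deadline=None)
    @given(
        triples=st.lists(
            st.tuples(
                st.from_regex(r"[A-Za-z0-9_.:-]{1,12}", fullmatch=True),
                st.text(alphabet=st.characters(whitelist_categories=("L", "N"),
                                               whitelist_characters=" "),
                        max_size=15),
                st.text(alphabet="ACGTN", min_size=1, max_size=120),
            ),
            min_size=1, max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_write_read_preserves_triples(self, triples, tmp_path_factory):
        records = [
            SequenceRecord(id=i, description=" ".join(d.split()), residues=s)
            for i, d, s in triples
        ]
        path = tmp_path_factory.mktemp("rt") / "x.fna"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.description, r.residues) for r in back] == [
            (r.id, r.description, r.residues) for r in records
        ]

    def test_empty_sequence_rejected(self):
        with pytest.raises(FastaError):
            SequenceRecord(id="x", description="", residues="")


class TestSplitFasta:
    @pytest.mark.parametrize(
        "n_records,batch,expected_sizes",
        [(10, 1, [1] * 10), (10, 4, [4, 4, 2]), (1, 5, [1]), (6, 3, [3, 3])],
    )
    def test_partition_round_trips(self, tmp_path, n_records, batch, expected_sizes):
        src = _write(tmp_path / "multi.fna", _records(n_records))
        outputs = split_fasta(src, batch_size=batch, output_dir=tmp_path / "parts")
        sizes = [len(read_fasta(p)) for p in outputs]
        assert sizes == expected_sizes
        merged = [r for p in outputs for r in read_fasta(p)]
        assert [(r.id, r.residues) for r in merged] == [
            (r.id, r.residues) for r in read_fasta(src)
        ]

    def test_batch_size_validation(self, tmp_path):
        src = _write(tmp_path / "multi.fna", _records(2))
        with pytest.raises(ValueError):
            split_fasta(src, batch_size=0)


class TestUniqueHeaders:
    def _collection(self, tmp_path, n_files=2, n_records=3, identical=False):
        for i in range(n_files):
            recs = [
                SequenceRecord(
                    id="hypothetical", description="protein",
                    residues=("MKV" * 10) if identical else ("MKV" * 10 + "ACDEFGHIKL"[j]),
                    molecule="protein",
                )
                for j in range(n_records)
            ]
            write_fasta(recs, tmp_path / f"genome{i}a.faa")
        return resolve_inputs(tmp_path)

    def test_shape_and_uniqueness(self, tmp_path):
        coll = self._collection(tmp_path)
        updated = assign_unique_headers(coll, seed=3)
        ids = [r.id for e in updated for r in read_fasta(e.path, molecule="protein")]
        assert len(ids) == len(set(ids)) == 6
        for rid in ids:
            base, stem, tag = rid.rsplit("_", 2)
            assert base == "hypothetical"
            assert stem in {"genome0a", "genome1a"}
            assert len(tag) == 5 and tag.isalnum()

    def test_deterministic_reruns_byte_identical(self, tmp_path):
        coll = self._collection(tmp_path)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        for out in (out1, out2):
            out.mkdir()
            assign_unique_headers(resolve_inputs(tmp_path / "genome0a.faa"),
                                  deterministic=True, output_dir=out)
        assert (out1 / "genome0a.faa").read_bytes() == (out2 / "genome0a.faa").read_bytes()

    def test_deterministic_distinct_residues_distinct_tags(self, tmp_path):
        coll = self._collection(tmp_path, n_files=1, n_records=3)
        updated = assign_unique_headers(coll, deterministic=True)
        ids = [r.id for e in updated for r in read_fasta(e.path, molecule="protein")]
        assert len(set(i.rsplit("_", 1)[1] for i in ids)) == 3

    def test_mass_collision_ids_globally_unique(self, tmp_path):
        # 10,000 records all sharing one header and one sequence
        recs = [SequenceRecord(id="dup", description="", residues="MKVLA" * 8,
                               molecule="protein") for _ in range(10_000)]
        write_fasta(recs, tmp_path / "dups.faa")
        updated = assign_unique_headers(resolve_inputs(tmp_path / "dups.faa"), seed=5)
        ids = [r.id for r in read_fasta(updated.entries[0].path, molecule="protein")]
        assert len(ids) == 10_000 and len(set(ids)) == 10_000
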