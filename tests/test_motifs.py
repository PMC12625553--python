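"""Wildcard motif DSL: parsing, scanning vs a brute-force oracle, planning, export."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastkit.fasta_io import read_fasta
from blastkit.motifs import (
    MotifError,
    export_motif_fasta,
    match_table,
    parse_motif_spec,
    parse_motif_token,
    plan_scans,
    scan_hits,
    scan_sequence,
)
from conftest import make_hit


def oracle_scan(residues: str, motif: str) -> list[tuple[int, str]]:
    """Brute-force window oracle: test every window of pattern length."""
    residues, motif = residues.upper(), motif.upper()
    out = []
    for start in range(len(residues) - len(motif) + 1):
        window = residues[start: start + len(motif)]
        if all(m == "X" or m == c for m, c in zip(motif, window)):
            out.append((start + 1, window))
    return out


def as_pairs(matches):
    return [(m.start, m.matched) for m in matches]


class TestParsing:
    def test_wildcards_and_binding(self):
        plain = parse_motif_token("WXWXIP")
        assert len(plain) == 6 and plain.binding is None
        assert plain.positions == ("W", None, "W", None, "I", "P")
        bound = parse_motif_token("RVXXXQ{AT}")
        assert bound.binding == "AT" and bound.motif == "RVXXXQ"

    def test_case_normalization(self):
        assert parse_motif_token("rvxxxq").positions == parse_motif_token("RVXXXQ").positions

    @pytest.mark.parametrize("bad", ["RV*Q", "RVQ{}", "RVQ{AT", "RVQ}AT{", "", "R1Q"])
    def test_malformed_tokens(self, bad):
        with pytest.raises(MotifError):
            parse_motif_token(bad)

    def test_non_standard_residue_letter(self):
        with pytest.raises(MotifError, match="standard one-letter"):
            parse_motif_token("RBQ")  # B is not one of the 20 codes

    def test_spec_parses_token_list(self):
        patterns = parse_motif_spec(["WXWXIP", "RVXXXQ{AT}"])
        assert [p.raw for p in patterns] == ["WXWXIP", "RVXXXQ{AT}"]


class TestScanning:
    @pytest.mark.parametrize(
        "residues,motif,expected",
        [
            ("RVEVVQ", "RVXXXQ", [(1, "RVEVVQ")]),
            ("HAAATLDDGSSFASAFGAPGLGGYAP", "SSXXXXXXXXXXXXYXX",
             [(10, "SSFASAFGAPGLGGYAP")]),
            ("AAAAA", "AXA", [(1, "AAA"), (2, "AAA"), (3, "AAA")]),
            ("MKVL", "WW", []),
        ],
    )
    def test_known_occurrences(self, residues, motif, expected):
        assert as_pairs(scan_sequence(residues, parse_motif_token(motif))) == expected

    def test_matches_oracle_on_random_cases(self):
        rng = random.Random(99)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(1000):
            seq = "".join(rng.choice(aas) for _ in range(rng.randint(1, 60)))
            motif = "".join(
                "X" if rng.random() < 0.5 else rng.choice(aas)
                for _ in range(rng.randint(1, 8))
            )
            got = as_pairs(scan_sequence(seq, parse_motif_token(motif)))
            assert got == oracle_scan(seq, motif)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 10), st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40))
    def test_all_wildcard_pattern_counts_windows(self, k, seq):
        pattern = parse_motif_token("X" * k)
        assert len(scan_sequence(seq, pattern)) == max(0, len(seq) - k + 1)

    def test_case_invariance(self):
        upper = as_pairs(scan_sequence("RVEVVQ", parse_motif_token("RVXXXQ")))
        lower = as_pairs(scan_sequence("rvevvq", parse_motif_token("rvxxxq")))
        assert upper == lower == [(1, "RVEVVQ")]

    def test_scans_degapped_subject(self):
        hit = make_hit(subject_residues="RV-EVVQ", program="blastp")
        matches = scan_hits(parse_motif_spec(["RVXXXQ"]), [hit])
        assert as_pairs(matches) == [(1, "RVEVVQ")]


class TestPlanning:
    def test_binding_restricts_to_query_stem(self):
        hits = [make_hit(query_file="AT"), make_hit(query_file="KS")]
        pattern = parse_motif_token("RVXXXQ{AT}")
        pairs = plan_scans([pattern], hits)
        assert [h.query_file for _, h in pairs] == ["AT"]

    def test_unbound_pattern_pairs_with_every_hit(self):
        hits = [make_hit(query_file=f"q{i}") for i in range(5)]
        pairs = plan_scans(parse_motif_spec(["WXWXIP"]), hits)
        assert len(pairs) == 5

    def test_unknown_binding_warns_and_yields_no_pairs(self, caplog):
        hits = [make_hit(query_file="AT")]
        with caplog.at_level("WARNING", logger="blastkit"):
            pairs = plan_scans([parse_motif_token("RVXXXQ{ZZ}")], hits)
        assert pairs == []
        assert any("ZZ" in rec.message for rec in caplog.records)

    def test_scanning_ignores_thresholds(self):
        # a hit far below default thresholds is still scanned
        weak = make_hit(pident=10.0, evalue=5.0, subject_residues="RVEVVQ",
                        program="tblastn")
        assert len(scan_hits(parse_motif_spec(["RVXXXQ"]), [weak])) == 1

    def test_refuses_blastn_subjects(self):
        hits = [make_hit(program="blastn", subject_residues="ACGTACGT")]
        with pytest.raises(MotifError, match="blastn"):
            plan_scans(parse_motif_spec(["RVXXXQ"]), hits)

    def test_accepts_blastp_and_tblastn(self):
        hits = [make_hit(program="blastp", subject_residues="RVEVVQ"),
                make_hit(program="tblastn", subject_residues="RVEVVQ")]
        assert len(scan_hits(parse_motif_spec(["RVXXXQ"]), hits)) == 2


class TestExport:
    def _matches(self):
        hits = [
            make_hit(subject_residues="MRVEVVQAA", sseqid="s1", database="db1",
                     program="blastp"),
            make_hit(subject_residues="GHSQGEKKK", sseqid="s2", database="db2",
                     program="blastp"),
        ]
        return scan_hits(parse_motif_spec(["RVXXXQ", "GHXXGE", "WXWXIP"]), hits)

    def test_one_fasta_per_matched_pattern(self, tmp_path):
        outputs = export_motif_fasta(self._matches(), tmp_path)
        # WXWXIP matched nothing, so only two files appear
        assert sorted(p.name for p in outputs) == ["motif_GHXXGE.faa", "motif_RVXXXQ.faa"]

    def test_motif_only_records_are_pattern_length(self, tmp_path):
        outputs = export_motif_fasta(self._matches(), tmp_path, motif_only=True)
        for path in outputs:
            for rec in read_fasta(path, molecule="protein"):
                assert len(rec.residues) == 6

    def test_default_records_carry_full_degapped_subject(self, tmp_path):
        outputs = export_motif_fasta(self._matches(), tmp_path)
        rv = next(p for p in outputs if "RVXXXQ" in p.name)
        assert read_fasta(rv, molecule="protein")[0].residues == "MRVEVVQAA"

    def test_match_table_columns(self):
        table = match_table(self._matches())
        assert list(table.columns) == [
            "motif", "database", "sseqid", "qseqid", "start", "end", "matched"
        ]
        assert set(table["matched"]) == {"RVEVVQ", "GHSQGE"}
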