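"""Germline database loading, SNP injection and reference pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import igsim
from igsim.germline import (
    SNP_REGION_BP,
    GermlineAllele,
    GermlineDatabase,
    SNPSpec,
    edit_distance,
    load_germline_fasta,
    read_truth_tsv,
    write_germline_fasta,
    write_truth_tsv,
)


def _brute_edit_distance(a: str, b: str) -> int:
    # independent O(nm) DP oracle for the edlib-backed distance
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestFastaIO:
    def test_parse_two_records_with_segments(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">IGHV-toy1*01\nACGTACG\n>IGHJ-toy1*01|something\nTTGACA\n")
        db = load_germline_fasta(p)
        assert len(db) == 2
        assert db["IGHV-toy1*01"].segment == "V"
        assert db["IGHJ-toy1*01"].segment == "J"

    def test_lowercase_and_gaps_normalized(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">IGHV-toy1*01\nac.g-t\n")
        assert load_germline_fasta(p)["IGHV-toy1*01"].sequence == "ACGT"

    def test_imgt_style_header_name_extraction(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">X123|IGHV1-2*02|Homo sapiens|F\nACGT\n")
        assert "IGHV1-2*02" in load_germline_fasta(p)

    def test_duplicate_name_raises(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">IGHV1-2*02\nACGT\n>IGHV1-2*02\nTTTT\n")
        with pytest.raises(ValueError, match="IGHV1-2\\*02"):
            load_germline_fasta(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            load_germline_fasta(p)

    def test_round_trip_identity(self, toy_db, tmp_path):
        out = tmp_path / "roundtrip.fasta"
        write_germline_fasta(toy_db, out)
        back = load_germline_fasta(out)
        assert back.names == toy_db.names
        assert all(back[n].sequence == toy_db[n].sequence for n in toy_db.names)


class TestNormalizeDegenerate:
    @pytest.mark.parametrize(
        "raw,expected",
        [("ACGT", "ACGT"), ("RNT", "AAT"), ("", ""), ("YSWKMBDHVU", "CCAGACAAAT")],
    )
    def test_mapping(self, raw, expected):
        assert igsim.normalize_degenerate(raw) == expected

    def test_non_iupac_raises(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            igsim.normalize_degenerate("ACX")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_length_preserved_and_plain(self, seq):
        out = igsim.normalize_degenerate(seq)
        assert len(out) == len(seq)
        assert set(out) <= set("ACGT")


class TestSNPNotation:
    def test_table_notation_examples(self):
        assert igsim.snp_notation(SNPSpec(92, "G", "A")) == "G92A"
        assert igsim.parse_snp_notation("C72G") == SNPSpec(72, "C", "G")

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            SNPSpec(10, "A", "A")

    @pytest.mark.parametrize("bad", ["G0A", "92A", "GA", "G-2A", "g72", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            igsim.parse_snp_notation(bad)

    @given(
        st.integers(min_value=1, max_value=280),
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, locus, ref, alt):
        if ref == alt:
            return
        snp = SNPSpec(locus, ref, alt)
        assert igsim.parse_snp_notation(igsim.snp_notation(snp)) == snp


class TestInjection:
    @pytest.mark.parametrize("n_snps", [1, 3, 5, 7])
    def test_loci_within_window_and_hamming(self, toy_db, n_snps):
        cdb, truths = igsim.inject_artificial_snps(
            toy_db, ["IGHV1-S*01", "IGHV2-S*01"], n_snps, seed=n_snps
        )
        for t in truths:
            assert len(t.snps) == n_snps
            assert len(set(t.snp_loci)) == n_snps
            assert all(1 <= l <= SNP_REGION_BP for l in t.snp_loci)
            altered = cdb[t.source_allele].sequence
            diffs = [
                i + 1
                for i, (a, b) in enumerate(zip(altered, t.novel_sequence))
                if a != b
            ]
            assert diffs == sorted(t.snp_loci)

    def test_novel_sequence_is_real_germline(self, toy_db):
        cdb, truths = igsim.inject_artificial_snps(toy_db, ["IGHV1-S*01"], 3, seed=0)
        assert truths[0].novel_sequence == toy_db["IGHV1-S*01"].sequence
        assert cdb["IGHV1-S*01"].sequence != toy_db["IGHV1-S*01"].sequence

    def test_snp_orientation_matches_customized_reference(self, toy_db):
        cdb, truths = igsim.inject_artificial_snps(toy_db, ["IGHV1-S*01"], 5, seed=2)
        t = truths[0]
        for snp in t.snps:
            assert cdb[t.source_allele].sequence[snp.locus - 1] == snp.ref
            assert t.novel_sequence[snp.locus - 1] == snp.alt

    def test_determinism(self, toy_db):
        a = igsim.inject_artificial_snps(toy_db, ["IGHV1-S*01"], 7, seed=42)
        b = igsim.inject_artificial_snps(toy_db, ["IGHV1-S*01"], 7, seed=42)
        assert a[1] == b[1]
        assert a[0]["IGHV1-S*01"].sequence == b[0]["IGHV1-S*01"].sequence

    def test_bad_targets_rejected(self, toy_db):
        with pytest.raises(KeyError):
            igsim.inject_artificial_snps(toy_db, ["IGHV99-S*01"], 1, seed=0)
        with pytest.raises(ValueError, match="not a V allele"):
            igsim.inject_artificial_snps(toy_db, ["IGHD1-S*01"], 1, seed=0)
        with pytest.raises(ValueError):
            igsim.inject_artificial_snps(toy_db, ["IGHV1-S*01"], 281, seed=0)

    def test_truth_tsv_round_trip(self, toy_db, tmp_path):
        _, truths = igsim.inject_artificial_snps(
            toy_db, ["IGHV1-S*01", "IGHV3-S*02"], 3, seed=9
        )
        path = tmp_path / "truth.tsv"
        write_truth_tsv(truths, path)
        assert read_truth_tsv(path) == truths


class TestPruneConfusable:
    def _mini_db(self, extra):
        v = "ACGTAC" * 50  # 300 bp
        alleles = [GermlineAllele("IGHV1-X*01", v, "V")] + extra
        return GermlineDatabase(alleles), v

    def test_identical_competitor_removed(self):
        db, v = self._mini_db([GermlineAllele("IGHV2-X*01", "ACGTAC" * 50, "V")])
        cdb, truths = igsim.inject_artificial_snps(db, ["IGHV1-X*01"], 1, seed=0)
        pruned, removed = igsim.prune_confusable(cdb, truths)
        # the untouched twin is distance 0 from the novel sequence, the
        # altered target distance 1 -> twin must go
        assert "IGHV2-X*01" not in pruned
        assert removed and removed[0][0] == "IGHV2-X*01"

    def test_distant_competitor_kept(self):
        far = "ACGTAC" * 50
        far = "TTTTT" + far[5:]
        db, _ = self._mini_db([GermlineAllele("IGHV2-X*01", far, "V")])
        cdb, truths = igsim.inject_artificial_snps(db, ["IGHV1-X*01"], 1, seed=0)
        pruned, removed = igsim.prune_confusable(cdb, truths)
        assert "IGHV2-X*01" in pruned
        assert removed == []

    def test_lone_target_unchanged(self):
        db, _ = self._mini_db([])
        cdb, truths = igsim.inject_artificial_snps(db, ["IGHV1-X*01"], 1, seed=0)
        pruned, removed = igsim.prune_confusable(cdb, truths)
        assert pruned.names == cdb.names

    def test_targets_never_pruned(self, toy_db):
        cdb, truths = igsim.inject_artificial_snps(
            toy_db, ["IGHV1-S*01", "IGHV1-S*02"], 1, seed=3
        )
        pruned, _ = igsim.prune_confusable(cdb, truths)
        assert "IGHV1-S*01" in pruned and "IGHV1-S*02" in pruned

    @given(st.text(alphabet="ACGT", min_size=0, max_size=12),
           st.text(alphabet="ACGT", min_size=0, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_edit_distance_matches_dp_oracle(self, a, b):
        assert edit_distance(a, b) == _brute_edit_distance(a, b)
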