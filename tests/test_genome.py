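"""Sequence container, ORF calling, translation and GC arithmetic."""

import numpy as np
import pytest

from plasmidkit.genome import (
    PlasmidRecord,
    ValidationError,
    find_orfs,
    gc_content,
    primary_orfs,
    read_sequences,
    reverse_complement,
    translate,
)

from .conftest import random_seq
from . import oracles


class TestReverseComplement:
    def test_palindrome_is_self_complementary(self):
        assert reverse_complement("AGCCTTGCAAGGCT") == "AGCCTTGCAAGGCT"

    def test_single_base(self):
        assert reverse_complement("A") == "T"

    def test_iupac_codes(self):
        assert reverse_complement("WYRN") == "NYRW"

    def test_involution_and_gc_symmetry(self):
        for seed in range(10):
            s = random_seq(seed, 100)
            assert reverse_complement(reverse_complement(s)) == s
            assert gc_content(s) == pytest.approx(
                gc_content(reverse_complement(s)))

    def test_rejects_non_iupac(self):
        with pytest.raises(ValidationError, match="position 2"):
            reverse_complement("AXG")


class TestGCContent:
    def test_extremes(self):
        assert gc_content("GCGC") == 100.0
        assert gc_content("ATAT") == 0.0

    def test_window_size_rule(self):
        # interval (start, end) covers bases start..end-1: size = end - start
        rec = PlasmidRecord("r", "ATGC" * 10, "linear")
        assert gc_content(rec, 1, 5) == 50.0   # "ATGC"
        assert gc_content(rec, 1, 3) == 0.0    # "AT"

    def test_ambiguous_bases_excluded(self):
        assert gc_content("GCNN") == 100.0

    def test_circular_wrap(self):
        rec = PlasmidRecord("r", "GGGGAAAA", "circular")
        # window wrapping the origin: bases 7,8,1,2 = A,A,G,G
        assert gc_content(rec, 7, 11) == 50.0

    def test_empty_window_rejected(self):
        rec = PlasmidRecord("r", "ACGT", "linear")
        with pytest.raises(ValidationError):
            gc_content(rec, 2, 2)


class TestTranslate:
    @pytest.mark.parametrize("nt,aa", [
        ("ATGGGCTAA", "MG"),
        ("GTGGGCTAA", "MG"),   # alternative start rendered as M
        ("TTGAAATAA", "MK"),
    ])
    def test_examples(self, nt, aa):
        assert translate(nt) == aa

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="internal stop"):
            translate("ATGTAAGGCTAA")

    def test_matches_codon_table_oracle(self):
        rng = np.random.default_rng(3)
        codons = []
        while len(codons) < 50:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if c not in oracles.STOPS:
                codons.append(c)
        nt = "ATG" + "".join(codons) + "TAA"
        assert translate(nt) == oracles.translate_oracle(nt)


class TestFindOrfs:
    def test_minimal_linear_orf(self):
        rec = PlasmidRecord("r", "ATGAAATAA", "linear")
        orfs = find_orfs(rec, min_codons=2)
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end, orf.strand) == (1, 9, "+")
        assert orf.length_codons == 3
        assert orf.aa_sequence == "MK"

    def test_no_start_codon(self):
        rec = PlasmidRecord("r", "CCCCCCCCCCCC", "linear")
        assert find_orfs(rec, min_codons=2) == []

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_bruteforce_oracle(self, seed):
        """Six-frame maximal-ORF calling equals the naive definition."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(200, 600))
        seq = random_seq(seed + 1000, length, gc=0.5)
        circular = bool(seed % 2)
        rec = PlasmidRecord("r", seq, "circular" if circular else "linear")
        got = {(o.start, o.end, o.strand) for o in find_orfs(rec, min_codons=10)}
        want = oracles.orf_oracle(seq, circular, min_codons=10)
        assert got == want

    def test_circular_rotation_shifts_coordinates(self):
        seq = random_seq(7, 900, gc=0.5)
        rec = PlasmidRecord("r", seq, "circular")
        base = {(o.start, o.end, o.strand, o.aa_sequence)
                for o in find_orfs(rec, min_codons=10)}
        k = 137
        rot = rec.rotate(k)
        n = len(seq)

        def unshift(p):
            return ((p - 1 + k) % n) + 1

        back = {(unshift(o.start), unshift(o.end), o.strand, o.aa_sequence)
                for o in find_orfs(rot, min_codons=10)}
        assert back == base

    def test_every_orf_retranslates_cleanly(self, annotated_plasmid):
        from plasmidkit.genome import orf_nt
        rec, _ = annotated_plasmid
        for orf in find_orfs(rec):
            aa = translate(orf_nt(rec, orf))
            assert aa == orf.aa_sequence

    def test_primary_selection_drops_nested_frames(self):
        rec = PlasmidRecord("r", "ATG" + "GCT" * 60 + "TAA", "linear")
        all_orfs = find_orfs(rec, min_codons=10)
        prim = primary_orfs(all_orfs, len(rec))
        assert len(prim) >= 1
        spans = [o.span(len(rec)) for o in prim]
        for i, (a, b) in enumerate(spans):
            for c, d in spans[i + 1:]:
                assert min(b, d) - max(a, c) <= 30


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">p1 test\n" + random_seq(1, 2925) + "\n")
        records = read_sequences(p)
        assert len(records) == 1
        assert records[0].id == "p1"
        assert len(records[0]) == 2925
        assert records[0].topology == "circular"

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_sequences(p) == []
        assert any("no sequences" in r.message for r in caplog.records)

    def test_illegal_character_rejected(self):
        with pytest.raises(ValidationError, match="position 3"):
            PlasmidRecord("r", "AC!T", "linear")
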