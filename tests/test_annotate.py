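"""Backbone module assembly: oriV/oriT prediction, TA pairs, classification."""

import pytest

from plasmidkit.annotate import (
    classify_modules,
    detect_ta_pairs,
    module_string,
    predict_oriT,
    predict_oriV,
    summarize,
)
from plasmidkit.genome import Orf, PlasmidRecord, find_orfs, gc_content, primary_orfs
from plasmidkit.islets import assign_orfs, detect_islets, gc_profile
from plasmidkit.simulate import (
    IsletSpec,
    MobSpec,
    PlasmidSpec,
    RepSpec,
    TASpec,
    generate_plasmid,
)

from .conftest import random_seq


def rep_orf_of(rec, truth):
    feat = truth.of_kind("rep_orf")[0]
    for orf in find_orfs(rec):
        if orf.strand == "+" and orf.span(len(rec)) == (feat.start0, feat.end0):
            return orf
    raise AssertionError("planted rep ORF not recovered")


class TestPredictOriV:
    def test_planted_oriv_scores_at_least_two(self):
        spec = PlasmidSpec(length=5000, background_gc=0.60, seed=2,
                           rep=RepSpec(n_units=3, unit_len=19, spacer=2,
                                       dnaA=True), islet=None)
        rec, truth = generate_plasmid(spec)
        pred = predict_oriV(rec, rep_orf_of(rec, truth))
        assert pred is not None
        assert pred.iteron_array is not None
        assert pred.iteron_array.n_units == 3
        assert pred.iteron_array.unit_length == 19
        assert pred.iteron_array.spacers == [2, 2]
        assert len(pred.dnaA_hits) >= 1
        assert pred.score >= 2

    def test_no_upstream_evidence_gives_none(self):
        # an ORF with featureless upstream sequence
        seq = random_seq(30, 2000, gc=0.5)
        body = "ATG" + "GCT" * 60 + "TAA"
        rec = PlasmidRecord("r", seq[:1197] + "TAA" + body + seq[1200:],
                            "circular")
        orf = next(o for o in find_orfs(rec, min_codons=30)
                   if o.strand == "+" and o.start == 1201)
        pred = predict_oriV(rec, orf)
        assert pred is None or pred.iteron_array is None

    def test_dnaA_box_never_lowers_score(self):
        for seed in (2, 3, 4):
            base = PlasmidSpec(length=5000, background_gc=0.60, seed=seed,
                               rep=RepSpec(dnaA=False), islet=None)
            plus = PlasmidSpec(length=5000, background_gc=0.60, seed=seed,
                               rep=RepSpec(dnaA=True), islet=None)
            rec0, tr0 = generate_plasmid(base)
            rec1, tr1 = generate_plasmid(plus)
            p0 = predict_oriV(rec0, rep_orf_of(rec0, tr0))
            p1 = predict_oriV(rec1, rep_orf_of(rec1, tr1))
            assert (p1.score if p1 else 0) >= (p0.score if p0 else 0)


class TestDetectTAPairs:
    @staticmethod
    def orf(start, end, strand, codons):
        return Orf(start=start, end=end, strand=strand, length_codons=codons,
                   aa_sequence="M" + "A" * (codons - 2))

    def test_four_bp_overlap(self):
        a = self.orf(101, 370, "+", 90)
        b = self.orf(367, 636, "+", 90)     # gap = 367 - 370 - 1 = -4
        pairs = detect_ta_pairs([a, b], 2000)
        assert len(pairs) == 1
        assert pairs[0].gap == -4
        assert pairs[0].architecture == "overlap"

    def test_ten_bp_intergenic(self):
        a = self.orf(101, 370, "+", 90)
        b = self.orf(381, 650, "+", 90)     # gap = +10
        pairs = detect_ta_pairs([a, b], 2000)
        assert len(pairs) == 1
        assert pairs[0].gap == 10
        assert pairs[0].architecture == "short_intergenic"

    def test_opposite_strands_excluded(self):
        a = self.orf(101, 370, "+", 90)
        b = self.orf(636, 367, "-", 90)
        assert detect_ta_pairs([a, b], 2000) == []

    def test_long_orfs_excluded(self):
        a = self.orf(101, 1003, "+", 301)
        b = self.orf(1000, 1269, "+", 90)
        assert detect_ta_pairs([a, b], 2000) == []


class TestPredictOriT:
    def test_planted_exact_consensus_hit(self):
        spec = PlasmidSpec(length=5000, background_gc=0.60, seed=4, rep=None,
                           mob=MobSpec(orit_mismatches=0), islet=None)
        rec, truth = generate_plasmid(spec)
        mob_feat = truth.of_kind("mob_orf")[0]
        orit_feat = truth.of_kind("oriT")[0]
        mob = next(o for o in find_orfs(rec)
                   if o.strand == "+"
                   and o.span(len(rec)) == (mob_feat.start0, mob_feat.end0))
        pred = predict_oriT(rec, mob)
        assert pred is not None
        assert pred.hit.mismatches == 0
        assert pred.site_start0 == orit_feat.start0
        assert pred.family_pattern == "oriT_MOBQ"

    def test_absent_consensus_gives_none(self):
        seq = random_seq(31, 1500, gc=0.5)
        body = "ATG" + "GCT" * 60 + "TAA"
        rec = PlasmidRecord("r", seq[:897] + "TAA" + body + seq[900:],
                            "circular")
        orf = next(o for o in find_orfs(rec, min_codons=30)
                   if o.strand == "+" and o.start == 901)
        assert predict_oriT(rec, orf) is None


class TestClassifyAndSummarize:
    def test_full_synthetic_modules(self, annotated_plasmid):
        rec, truth = annotated_plasmid
        orfs = primary_orfs(find_orfs(rec), len(rec))
        islets = detect_islets(gc_profile(rec), rec)
        assign_orfs(islets, orfs, len(rec))
        modules = classify_modules(rec, orfs=orfs, islets=islets)
        kinds = {m.kind for m in modules}
        assert {"REP", "MOB", "TA"} <= kinds
        # islet-resident ORFs carry the PI flag
        pi = [m for m in modules if m.kind == "ACCESSORY" and m.label == "PI"]
        assert pi

    def test_random_record_all_accessory(self):
        rec = PlasmidRecord("r", random_seq(33, 4000, gc=0.5), "circular")
        modules = classify_modules(rec)
        assert {m.kind for m in modules} == {"ACCESSORY"}
        assert module_string(modules) == "—"

    def test_every_orf_in_exactly_one_module(self, annotated_plasmid):
        rec, _ = annotated_plasmid
        orfs = primary_orfs(find_orfs(rec), len(rec))
        modules = classify_modules(rec, orfs=orfs, islets=[])
        seen = []
        for m in modules:
            for member in m.members:
                if isinstance(member, Orf):
                    seen.append(id(member))
                elif hasattr(member, "orf_a"):
                    seen.extend([id(member.orf_a), id(member.orf_b)])
        assert sorted(seen) == sorted(id(o) for o in orfs)

    def test_summary_row_consistency(self, annotated_plasmid):
        rec, _ = annotated_plasmid
        orfs = primary_orfs(find_orfs(rec), len(rec))
        islets = detect_islets(gc_profile(rec), rec)
        assign_orfs(islets, orfs, len(rec))
        modules = classify_modules(rec, orfs=orfs, islets=islets)
        row = summarize(rec, modules, islets, orfs)
        assert row["size_bp"] == len(rec)
        assert row["gc_pct"] == pytest.approx(gc_content(rec), abs=0.05)
        assert row["n_orfs"] == len(orfs)
        assert "REP" in row["modules"]
        assert len(row["islets"]) == len(islets)
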