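"""Assembly of cis-elements and ORFs into typed plasmid backbone modules.

The classifier is purely structural: a REP module is an ORF with a
credible replication-origin signature upstream (iteron array, inverted
repeats, DnaA/IHF boxes); a MOB module is an ORF with an oriT consensus
hit upstream; a TA module is a pair of short same-strand ORFs that
overlap or sit a few bases apart; a PAR module is a Walker-A ATPase next
to a short ORF with a parS-like repeat array upstream.  Remaining ORFs
are ACCESSORY, flagged PI when they sit inside a low-GC islet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from plasmidkit.genome import (
    Orf,
    PlasmidRecord,
    ValidationError,
    find_orfs,
    gc_content,
    primary_orfs,
)
from plasmidkit.islets import GCIslet, assign_orfs, detect_islets, gc_profile
from plasmidkit.motifs import MotifHit, MotifPattern, builtin_patterns, scan_motif
from plasmidkit.repeats import (
    InvertedRepeat,
    RepeatArray,
    find_direct_repeats,
    find_inverted_repeats,
)

log = logging.getLogger("plasmidkit")

ORIV_WINDOW = 600
ORIT_WINDOW = 500
TA_MIN_CODONS = 40
TA_MAX_CODONS = 200
TA_MAX_GAP = 30
TA_MAX_OVERLAP = -20
PARTIAL_ITERON_MIN_FRACTION = 0.60
PARTIAL_ITERON_NEAR_START = 60

PRECEDENCE = ["REP", "MOB", "PAR", "TA", "RM", "ACCESSORY"]


@dataclass
class OriVPrediction:
    rep_orf: Orf
    region: tuple[int, int]            # 1-based inclusive upstream window
    iteron_array: Optional[RepeatArray]
    inverted_repeats: list[InvertedRepeat]
    dnaA_hits: list[MotifHit]
    ihf_hits: list[MotifHit]
    partial_inverted_iteron: Optional[MotifHit]
    score: int


@dataclass
class TAPair:
    orf_a: Orf
    orf_b: Orf
    gap: int
    architecture: str   # overlap | short_intergenic


@dataclass
class OriTPrediction:
    mob_orf: Orf
    hit: MotifHit
    family_pattern: str
    site_start0: int = -1    # forward-strand zero-based position of the site
    distance_to_orf: int = 0


@dataclass
class GeneticModule:
    kind: str
    members: list = field(default_factory=list)
    label: str = ""


def _upstream_window(record: PlasmidRecord, orf: Orf, window: int) -> tuple[str, tuple[int, int], int]:
    """Sequence upstream of an ORF's start codon, on the ORF's strand.

    Returns (sequence 5'->3' toward the start codon, forward-strand
    1-based inclusive region, forward offset of the window start).
    """
    n = len(record)
    if orf.strand == "+":
        hi = orf.start - 1            # zero-based, exclusive of start codon
        lo = hi - window
        if not record.is_circular:
            lo = max(lo, 0)
        seq = record.window(lo, hi) if hi > lo else ""
        return seq, ((lo % n) + 1, ((hi - 1) % n) + 1), lo % n
    # minus strand: upstream is to the right on the forward strand
    lo = orf.start                    # zero-based position after start codon
    hi = lo + window
    if not record.is_circular:
        hi = min(hi, n)
    seq = record.window(lo, hi) if hi > lo else ""
    from plasmidkit.genome import reverse_complement
    return reverse_complement(seq), ((lo % n) + 1, ((hi - 1) % n) + 1), lo % n


def predict_oriV(record: PlasmidRecord, rep_orf: Orf,
                 window: int = ORIV_WINDOW,
                 patterns: dict[str, MotifPattern] | None = None) -> Optional[OriVPrediction]:
    """Score the structural replication-origin signature upstream of an ORF.

    Criteria counted: (i) an iteron array of >= 2 units, (ii) an inverted
    repeat, (iii) a DnaA-box hit, (iv) an IHF-box hit, (v) a partial
    inverted iteron adjacent to the start codon.  Returns None when no
    criterion is met.
    """
    patterns = patterns or builtin_patterns()
    up_seq, region, _ = _upstream_window(record, rep_orf, window)
    if not up_seq:
        return None
    arrays = find_direct_repeats(up_seq)
    array = max(arrays, key=lambda r: (r.n_units, r.unit_length)) if arrays else None
    irs = find_inverted_repeats(up_seq, min_arm=8, max_loop=30, max_mismatch=1)
    dnaA = [h for h in scan_motif(up_seq, patterns["dnaA_box"]) if h.strand == "+"]
    ihf = [h for h in scan_motif(up_seq, patterns["ihf_box_pMOS6"])
           if h.strand == "+" and h.mismatches <= 2]

    partial = None
    if array is not None:
        from plasmidkit.genome import reverse_complement
        min_len = max(8, int(PARTIAL_ITERON_MIN_FRACTION * array.unit_length))
        tail = up_seq[-(PARTIAL_ITERON_NEAR_START + array.unit_length):]
        rc = reverse_complement(array.consensus)
        for trunc_len in range(array.unit_length, min_len - 1, -1):
            for off in (0, array.unit_length - trunc_len):
                probe = rc[off:off + trunc_len]
                pos = tail.find(probe)
                if pos >= 0:
                    partial = MotifHit("partial_inverted_iteron",
                                       len(up_seq) - len(tail) + pos + 1,
                                       "+", 0, probe)
                    break
            if partial:
                break

    score = sum([
        array is not None and array.n_units >= 2,
        bool(irs),
        bool(dnaA),
        bool(ihf),
        partial is not None,
    ])
    if score < 1:
        return None
    return OriVPrediction(rep_orf=rep_orf, region=region, iteron_array=array,
                          inverted_repeats=irs, dnaA_hits=dnaA, ihf_hits=ihf,
                          partial_inverted_iteron=partial, score=score)


def _strand_gap(a: Orf, b: Orf, n: int) -> int | None:
    """Signed intergenic bp between two same-strand ORFs, a upstream of b."""
    if a.strand != b.strand:
        return None
    if a.strand == "+":
        return b.start - a.end - 1
    return a.end - b.start - 1


def detect_ta_pairs(orfs: list[Orf], seq_len: int,
                    min_codons: int = TA_MIN_CODONS,
                    max_codons: int = TA_MAX_CODONS,
                    max_gap: int = TA_MAX_GAP) -> list[TAPair]:
    """Same-strand adjacent short-ORF pairs with a small gap or overlap."""
    short = [o for o in orfs if min_codons <= o.length_codons <= max_codons]
    pairs = []
    for a in short:
        for b in short:
            if a is b:
                continue
            gap = _strand_gap(a, b, seq_len)
            if gap is None or not (TA_MAX_OVERLAP <= gap <= max_gap):
                continue
            arch = "overlap" if gap < 0 else "short_intergenic"
            pairs.append(TAPair(orf_a=a, orf_b=b, gap=gap, architecture=arch))
    pairs.sort(key=lambda p: (p.orf_a.start, p.orf_b.start))
    return pairs


def predict_oriT(record: PlasmidRecord, mob_orf: Orf,
                 patterns: list[MotifPattern] | None = None,
                 window: int = ORIT_WINDOW) -> Optional[OriTPrediction]:
    """Best oriT consensus hit upstream of a candidate relaxase gene."""
    if patterns is None:
        lib = builtin_patterns()
        patterns = [lib[k] for k in ("oriT_MOBQ", "oriT_MOBQ3", "oriT_MOBP5",
                                     "oriT_MOBV")]
    up_seq, _, offset = _upstream_window(record, mob_orf, window)
    if not up_seq:
        return None
    n = len(record)
    best: tuple[tuple[int, int], OriTPrediction] | None = None
    for pat in patterns:
        for hit in scan_motif(up_seq, pat):
            if hit.strand != "+":
                continue
            dist_to_start = len(up_seq) - (hit.start - 1 + len(pat))
            if mob_orf.strand == "+":
                site0 = (offset + hit.start - 1) % n
            else:
                site0 = (offset + len(up_seq) - (hit.start - 1) - len(pat)) % n
            key = (hit.mismatches, dist_to_start)
            if best is None or key < best[0]:
                best = (key, OriTPrediction(mob_orf=mob_orf, hit=hit,
                                            family_pattern=pat.name,
                                            site_start0=site0,
                                            distance_to_orf=dist_to_start))
    return best[1] if best else None


def _find_parS(record: PlasmidRecord, orf: Orf) -> Optional[RepeatArray]:
    up_seq, _, _ = _upstream_window(record, orf, 300)
    if not up_seq:
        return None
    arrays = find_direct_repeats(up_seq, min_unit=10, max_spacer=10,
                                 max_mismatch=1)
    for arr in sorted(arrays, key=lambda r: -r.n_units):
        if arr.n_units >= 3 and 10 <= arr.unit_length <= 16:
            return arr
    return None


def classify_modules(record: PlasmidRecord,
                     orfs: list[Orf] | None = None,
                     islets: list[GCIslet] | None = None,
                     patterns: dict[str, MotifPattern] | None = None) -> list[GeneticModule]:
    """Rule-based assembly of ORFs into typed backbone modules.

    Precedence on conflict: REP > MOB > PAR > TA > RM > ACCESSORY; every
    ORF ends up in exactly one module.
    """
    patterns = patterns or builtin_patterns()
    if orfs is None:
        orfs = primary_orfs(find_orfs(record), len(record))
    if islets is None:
        try:
            islets = detect_islets(gc_profile(record), record)
        except ValidationError:
            islets = []
        assign_orfs(islets, orfs, len(record))

    n = len(record)
    claimed: dict[int, str] = {}
    modules: list[GeneticModule] = []

    def claim(idx: int, kind: str) -> bool:
        if idx in claimed:
            prev = claimed[idx]
            if PRECEDENCE.index(kind) < PRECEDENCE.index(prev):
                log.info("%s: ORF %d reassigned %s -> %s by precedence",
                         record.id, idx, prev, kind)
                claimed[idx] = kind
                return True
            log.info("%s: ORF %d stays %s over %s", record.id, idx, prev, kind)
            return False
        claimed[idx] = kind
        return True

    # REP: ORF with an accepted oriV prediction.  Acceptance is anchored
    # on a real cis structure — an iteron array, or (for iteron-less
    # replication origins) a long inverted repeat — because short IRs and
    # single degenerate host-factor boxes arise freely in random sequence.
    oriv_by_orf: dict[int, OriVPrediction] = {}
    for i, orf in enumerate(orfs):
        pred = predict_oriV(record, orf, patterns=patterns)
        if pred is None:
            continue
        has_iterons = (pred.iteron_array is not None
                       and pred.iteron_array.n_units >= 2)
        has_long_ir = any(ir.arm_length >= 14 for ir in pred.inverted_repeats)
        if has_iterons or has_long_ir:
            oriv_by_orf[i] = pred
    if oriv_by_orf:
        best_i = max(oriv_by_orf, key=lambda i: (oriv_by_orf[i].score,
                                                 orfs[i].length_codons))
        if claim(best_i, "REP"):
            modules.append(GeneticModule("REP", [orfs[best_i], oriv_by_orf[best_i]],
                                         "rep + predicted oriV"))

    # MOB: ORF with an oriT prediction upstream.  Each oriT site belongs
    # to the single nearest downstream ORF (its relaxase gene); without
    # this, every ORF within the window of a site would be called MOB.
    orit_candidates: dict[int, OriTPrediction] = {}
    for i, orf in enumerate(orfs):
        if i in claimed:
            continue
        pred = predict_oriT(record, orf)
        if pred:
            orit_candidates[i] = pred
    by_site: dict[int, int] = {}
    for i, pred in orit_candidates.items():
        cur = by_site.get(pred.site_start0)
        if cur is None or (pred.hit.mismatches, pred.distance_to_orf) < (
                orit_candidates[cur].hit.mismatches,
                orit_candidates[cur].distance_to_orf):
            by_site[pred.site_start0] = i
    for i in sorted(by_site.values()):
        pred = orit_candidates[i]
        if claim(i, "MOB"):
            modules.append(GeneticModule("MOB", [orfs[i], pred],
                                         f"mob + {pred.family_pattern}"))

    # PAR: Walker-A ATPase adjacent to a short ORF, parS array upstream
    walker = patterns["walker_A_deviant"]
    for i, orf in enumerate(orfs):
        if i in claimed:
            continue
        if not scan_motif(orf.aa_sequence, walker):
            continue
        partner = None
        for j, other in enumerate(orfs):
            if j == i or j in claimed or other.length_codons > 150:
                continue
            gap = _strand_gap(orf, other, n)
            if gap is not None and -20 <= gap <= 100:
                partner = j
                break
        parS = _find_parS(record, orf)
        if partner is not None and parS is not None:
            if claim(i, "PAR") and claim(partner, "PAR"):
                modules.append(GeneticModule(
                    "PAR", [orfs[i], orfs[partner], parS], "parAB + parS"))

    # TA: accepted adjacent short-ORF pairs, tightest coupling first
    # (genuine TA operons overlap or sit a few bases apart)
    ta_candidates = detect_ta_pairs(
        [o for i, o in enumerate(orfs) if i not in claimed], n)
    ta_candidates.sort(key=lambda p: (abs(p.gap), p.orf_a.start))
    for pair in ta_candidates:
        ia = orfs.index(pair.orf_a)
        ib = orfs.index(pair.orf_b)
        if ia in claimed or ib in claimed:
            continue
        if claim(ia, "TA") and claim(ib, "TA"):
            modules.append(GeneticModule("TA", [pair], pair.architecture))

    # RM: adjacent pair where one product carries the m5C Pro-Cys dipeptide
    pc = patterns["m5C_motif_IV"]
    for i, orf in enumerate(orfs):
        if i in claimed or not scan_motif(orf.aa_sequence, pc):
            continue
        for j, other in enumerate(orfs):
            if j == i or j in claimed:
                continue
            gap = _strand_gap(orf, other, n)
            if gap is not None and -20 <= gap <= 30 and orf.length_codons >= 200:
                if claim(i, "RM") and claim(j, "RM"):
                    modules.append(GeneticModule("RM", [orf, other],
                                                 "m5C MTase + endonuclease"))
                break

    # everything else is accessory; islet residents get the PI flag
    islet_orfs = {id(o) for islet in (islets or []) for o in islet.contained_orfs}
    for i, orf in enumerate(orfs):
        if i in claimed:
            continue
        claimed[i] = "ACCESSORY"
        label = "PI" if id(orf) in islet_orfs else ""
        modules.append(GeneticModule("ACCESSORY", [orf], label))
    return modules


def module_string(modules: list[GeneticModule]) -> str:
    """Table-1-style module summary, e.g. 'REP, MOB, TA(2)'."""
    counts: dict[str, int] = {}
    for m in modules:
        if m.kind != "ACCESSORY":
            counts[m.kind] = counts.get(m.kind, 0) + 1
    order = [k for k in ("REP", "MOB", "PAR", "TA", "RM") if k in counts]
    if not order:
        return "—"
    return ", ".join(k if counts[k] == 1 else f"{k}({counts[k]})" for k in order)


def summarize(record: PlasmidRecord, modules: list[GeneticModule],
              islets: list[GCIslet], orfs: list[Orf]) -> dict:
    """One Table-1-style summary row plus a Table-2-style islet section."""
    return {
        "plasmid": record.id,
        "size_bp": len(record),
        "gc_pct": round(gc_content(record), 1),
        "n_orfs": len(orfs),
        "modules": module_string(modules),
        "islets": [
            {
                "size_bp": islet.size,
                "interval": (islet.start, islet.end),
                "islet_gc": islet.islet_gc,
                "remaining_gc": islet.background_gc,
                "orfs_aa": [o.length_codons - 1 for o in islet.contained_orfs],
            }
            for islet in islets
        ],
    }
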