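"""Synthetic circular plasmids with planted, ground-truthed backbone features.

The generator emulates the architecture of small mobilizable plasmids:
a 3-15 kb circular replicon with a 55-65% GC backbone, a rep gene
preceded by a tandem iteron array (with optional DnaA box and inverted
repeat), a mob gene preceded by a concrete oriT consensus instance, a
toxin-antitoxin pair of two short same-strand ORFs (small overlap or
short intergenic gap), an optional partitioning cassette (deviant Walker
A ATPase + parS repeats), and a low-GC islet carrying its own ORFs.

Every feature's exact coordinates are recorded in a :class:`TruthRecord`,
so detector recall can be measured without any reference database.  A
single integer seed drives one generator stream; identical specs and
seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from plasmidkit.genome import (
    PlasmidRecord,
    STOP_CODONS,
    ValidationError,
    find_orfs,
    primary_orfs,
    reverse_complement,
)
from plasmidkit.motifs import IUPAC_SETS, builtin_patterns

DNAA_INSTANCE = "TTATCCACA"  # exact expansion of the DnaA box consensus

# codons for the deviant Walker A peptide KGGSGKS
_WALKER_A_CODONS = "AAAGGTGGTTCTGGTAAATCT"


@dataclass
class RepSpec:
    orf_codons: int = 150
    n_units: int = 3
    unit_len: int = 19
    spacer: int = 2
    dnaA: bool = True
    ir_arm: int = 0      # 0 = no inverted repeat
    ir_loop: int = 14


@dataclass
class MobSpec:
    orf_codons: int = 120
    orit_family: str = "oriT_MOBQ"
    orit_mismatches: int = 0


@dataclass
class TASpec:
    len_a: int = 90      # codons, first (upstream) ORF
    len_b: int = 90
    gap: int = -4        # signed bp; negative = overlap (supported: -1, -4, >=0)


@dataclass
class IsletSpec:
    length: int = 2000
    gc: float = 0.40
    n_orfs: int = 1


@dataclass
class ParSpec:
    walker_a: bool = True
    parS_units: int = 3
    parS_unit_len: int = 13


@dataclass
class PlasmidSpec:
    """Study conditions for one synthetic plasmid."""

    length: int = 6000
    background_gc: float = 0.60
    seed: int = 1
    rep: Optional[RepSpec] = field(default_factory=RepSpec)
    mob: Optional[MobSpec] = None
    ta: Optional[TASpec] = None
    islet: Optional[IsletSpec] = field(default_factory=IsletSpec)
    par: Optional[ParSpec] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.background_gc < 1.0):
            raise ValidationError("background_gc must be in (0, 1)")
        if self.length < 1000:
            raise ValidationError("length must be >= 1000 bp")


@dataclass
class TruthFeature:
    kind: str
    start0: int          # zero-based half-open on the emitted sequence
    end0: int
    strand: str = "+"
    payload: dict = field(default_factory=dict)

    @property
    def start(self) -> int:  # 1-based first base
        return self.start0 + 1

    @property
    def end(self) -> int:    # 1-based last base
        return self.end0


@dataclass
class TruthRecord:
    features: list[TruthFeature]

    def of_kind(self, kind: str) -> list[TruthFeature]:
        return [f for f in self.features if f.kind == kind]

    def validate(self, sequence: str) -> None:
        for f in self.features:
            if not (0 <= f.start0 < f.end0 <= len(sequence)):
                raise ValidationError(f"truth feature {f.kind} out of range")
            if "sequence" in f.payload:
                if sequence[f.start0:f.end0] != f.payload["sequence"]:
                    raise ValidationError(f"truth feature {f.kind} sequence mismatch")


def _bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


# Codon sampling for planted genes avoids creating start codons in the
# five shadow frames (forward starts at shifted offsets; CAT/CAC/CAA are
# reverse-strand starts).  Shifted stop codons still arise freely, so any
# read-through from flanking sequence terminates quickly; the result is
# that planted ORFs are the maximal coding structures of their region, a
# property real genes get from codon bias.
_FORBIDDEN_CROSS = {"ATG", "GTG", "TTG", "CAT", "CAC", "CAA"}
_FORBIDDEN_CODON = STOP_CODONS | {"CAT", "CAC", "CAA"}


def _codon(rng: np.random.Generator, gc: float, first: str | None = None,
           ctx: str = "", ends_a: bool = False) -> str:
    # rejection of stop/shadow-start codons discards AT-rich draws and
    # raises realized GC; compensate at the proposal stage (calibrated
    # so whole-record GC is unbiased)
    gc = max(0.05, gc - 0.02)
    for _ in range(500):
        c = (first or "") + _bases(rng, 3 - len(first or ""), gc)
        if c in _FORBIDDEN_CODON:
            continue
        if ends_a and c[2] != "A":
            continue
        probe = ctx[-2:] + c
        if any(probe[i:i + 3] in _FORBIDDEN_CROSS
               for i in range(len(probe) - 3)):
            continue
        return c
    raise ValidationError("codon sampling failed under frame constraints")


# Insulating "stop walls": fixed sense-codon blocks whose shifted-frame
# trigrams are stop codons.  The start wall stops the two forward shadow
# frames (TAG at offsets 1 and 2), the end wall stops all three reverse
# frames (CTA = reverse-complemented TAG at offsets 0, 1 and 2), so a
# spurious reading frame entering a planted gene from either flank
# terminates within a few codons instead of running through it.
_START_WALL = ("CTA", "GCT", "AGC")          # Leu-Ala-Ser
_END_WALL = ("CCT", "ACC", "TAC", "CTA")     # Pro-Thr-Tyr-Leu


def _seam_ok(prev: str, block: str) -> bool:
    s = prev[-2:] + block[:2]
    return not any(s[i:i + 3] in _FORBIDDEN_CROSS for i in range(len(s) - 2))


def _orf_nt(rng: np.random.Generator, n_codons: int, gc: float,
            body_override: dict[int, str] | None = None,
            penult_ends_a: bool = False, stop: str = "TAA",
            first_base: str | None = None) -> str:
    """Start..stop nucleotides of an ORF of ``n_codons`` codons (incl. stop)."""
    n_body = n_codons - 2
    override = dict(body_override or {})
    if n_body >= 14:
        if not any(k in override for k in (1, 2, 3)):
            for i, c in enumerate(_START_WALL):
                override[1 + i] = c
        if not any(k in override for k in range(n_body - 5, n_body - 1)):
            for i, c in enumerate(_END_WALL):
                override[n_body - 5 + i] = c

    parts = ["ATG"]
    for k in range(n_body):
        ctx = parts[-1][-2:]
        if k in override:
            block = override[k]
            # the previous codon may form a forbidden trigram across the
            # seam; resample it (it is always a free, sampled codon)
            for _ in range(100):
                if _seam_ok(parts[-1], block) or len(parts) < 2 \
                        or (k - 1) in override:
                    break
                prev_ctx = parts[-2][-2:]
                parts[-1] = _codon(rng, gc, ctx=prev_ctx,
                                   first=first_base if k - 1 == 0 else None)
            parts.append(block)
        elif k == 0 and first_base:
            parts.append(_codon(rng, gc, first=first_base, ctx=ctx))
        elif penult_ends_a and k == n_body - 1:
            parts.append(_codon(rng, gc, ctx=ctx, ends_a=True))
        else:
            parts.append(_codon(rng, gc, ctx=ctx))
    parts.append(stop)
    return "".join(parts)


def _expand_consensus(rng: np.random.Generator, pattern_name: str,
                      mismatches: int) -> str:
    """A concrete instance of a library consensus, with planted mismatches."""
    pat = builtin_patterns()[pattern_name]
    out = [sorted(slot)[rng.integers(len(slot))] for slot in pat.slots]
    # plant mismatches at the most-constrained positions (never at N slots)
    fixed = [i for i, slot in enumerate(pat.slots) if len(slot) < 4]
    rng.shuffle(fixed)
    for i in fixed[:mismatches]:
        forbidden = pat.slots[i]
        choices = [b for b in "ACGT" if b not in forbidden]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_GUARD = "TAA"  # in-frame stop placed before each planted ORF


class _Builder:
    def __init__(self, rng: np.random.Generator, gc: float):
        self.rng = rng
        self.gc = gc
        self.parts: list[str] = []
        self.pos = 0
        self.truth: list[TruthFeature] = []

    def emit(self, s: str) -> int:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return start

    def pad(self, n: int) -> None:
        """Fill ``n`` bp of backbone.

        Long stretches are packed with accessory filler genes separated
        by 50-90 bp intergenic gaps, mirroring the gene-dense backbones
        of real plasmids; only short gaps stay purely random.
        """
        rng = self.rng
        while n >= 480:
            g = int(rng.integers(50, 91))
            codons = int(min((n - g - 63) // 3, rng.integers(100, 201)))
            if codons < 60:
                break
            self.emit(_bases(rng, g - 3, self.gc) + _GUARD)
            orf = _orf_nt(rng, codons, self.gc)
            s = self.emit(orf)
            self.feature("accessory_orf", s, len(orf), sequence=orf)
            n -= g + len(orf)
        self.emit(_bases(rng, n, self.gc))

    def feature(self, kind: str, start0: int, length: int, **payload) -> None:
        self.truth.append(TruthFeature(kind, start0, start0 + length,
                                       payload=payload))


def _iteron_array(rng: np.random.Generator, n_units: int, unit_len: int,
                  spacer: int, gc: float) -> tuple[str, str]:
    """A tandem array whose unit boundaries are unambiguous.

    Maximal-extension repeat finders absorb a spacer base into the unit
    whenever two occurrences share the base flanking a unit boundary, so
    the bases immediately before and after each occurrence are made
    pairwise distinct (possible for up to 4 occurrences; beyond that the
    flanking bases cycle and a one-base boundary shift may be reported).
    """
    unit = _bases(rng, unit_len, gc)
    bases = list("ACGT")
    pre = [bases[i] for i in rng.permutation(4)]
    post = [bases[i] for i in rng.permutation(4)]
    pre = [pre[i % 4] for i in range(n_units)]
    post = [post[i % 4] for i in range(n_units)]
    parts = [pre[0]]
    for k in range(n_units):
        if k:
            middle = _bases(rng, max(spacer - 2, 0), gc)
            parts.append((post[k - 1] + middle + pre[k])[:max(spacer, 1)]
                         if spacer >= 1 else "")
        parts.append(unit)
    parts.append(post[n_units - 1])
    return "".join(parts), unit


def _build_rep(b: _Builder, spec: RepSpec) -> None:
    rng = b.rng
    arr, unit = _iteron_array(rng, spec.n_units, spec.unit_len, spec.spacer,
                              b.gc)
    if spec.ir_arm:
        arm = _bases(rng, spec.ir_arm, b.gc)
        ir = arm + _bases(rng, spec.ir_loop, b.gc) + reverse_complement(arm)
        start = b.emit(ir)
        b.feature("oriv_ir", start, len(ir), arm=spec.ir_arm, loop=spec.ir_loop)
        b.pad(int(rng.integers(5, 15)))
    start = b.emit(arr)
    # arr carries one boundary-disambiguation base on each side; the
    # iteron array proper is the interior
    b.feature("oriv_iterons", start + 1, len(arr) - 2, n_units=spec.n_units,
              unit_len=spec.unit_len, spacer=spec.spacer, unit=unit,
              sequence=arr[1:-1])
    if spec.dnaA:
        b.pad(2)
        start = b.emit(DNAA_INSTANCE)
        b.feature("dnaA_box", start, len(DNAA_INSTANCE), sequence=DNAA_INSTANCE)
    b.pad(int(rng.integers(20, 40)))
    b.emit(_GUARD)
    orf = _orf_nt(rng, spec.orf_codons, b.gc)
    start = b.emit(orf)
    b.feature("rep_orf", start, len(orf), sequence=orf)


def _build_mob(b: _Builder, spec: MobSpec) -> None:
    rng = b.rng
    orit = _expand_consensus(rng, spec.orit_family, spec.orit_mismatches)
    start = b.emit(orit)
    b.feature("oriT", start, len(orit), family=spec.orit_family,
              mismatches=spec.orit_mismatches, sequence=orit)
    b.pad(int(rng.integers(15, 30)))
    b.emit(_GUARD)
    orf = _orf_nt(rng, spec.orf_codons, b.gc)
    start = b.emit(orf)
    b.feature("mob_orf", start, len(orf), sequence=orf)


def _ta_cassette(rng: np.random.Generator, spec: TASpec,
                 gc: float) -> tuple[str, int, int, str, str]:
    """One candidate TA cassette: (seq, offset_a, offset_b, orf_a, orf_b)."""
    if spec.gap >= 0:
        orf_a = _orf_nt(rng, spec.len_a, gc)
        if spec.gap >= 3:
            linker = _bases(rng, spec.gap - 3, gc) + _GUARD
        else:
            linker = _bases(rng, spec.gap, gc)
        orf_b = _orf_nt(rng, spec.len_b, gc)
        seq = _GUARD + orf_a + linker + orf_b
        oa = len(_GUARD)
        ob = oa + len(orf_a) + spec.gap
    elif spec.gap == -1:
        # stop of A ends with the A of B's ATG: ...TGA|TG...
        orf_a = _orf_nt(rng, spec.len_a, gc, stop="TGA")
        rest = _orf_nt(rng, spec.len_b, gc)[3:]   # body after ATG
        orf_b = "ATG" + rest
        seq = _GUARD + orf_a + "TG" + rest
        oa = len(_GUARD)
        ob = oa + len(orf_a) - 1
    elif spec.gap == -4:
        # A ends ...A TGA so its last four bases read ATGA: B's start codon
        # sits inside A's stop region; classic relBE/parDE layout
        orf_a = _orf_nt(rng, spec.len_a, gc, penult_ends_a=True, stop="TGA")
        orf_b = _orf_nt(rng, spec.len_b, gc, first_base="A")
        seq = _GUARD + orf_a + orf_b[4:]
        oa = len(_GUARD)
        ob = oa + len(orf_a) - 4
    else:
        raise ValidationError("supported TA overlaps are -1, -4 or gaps >= 0")
    return seq, oa, ob, orf_a, orf_b


def _extends_upstream(seq: str, start: int) -> bool:
    """True when an in-frame start codon upstream of ``start`` (with no
    intervening stop, within this cassette) would absorb the planted ORF."""
    p = start - 3
    while p >= 0:
        codon = seq[p:p + 3]
        if codon in STOP_CODONS:
            return False
        if codon in ("ATG", "GTG", "TTG"):
            return True
        p -= 3
    return True  # ran into unknown flanking sequence: treat as unsafe


def _build_ta(b: _Builder, spec: TASpec) -> None:
    for _ in range(200):
        seq, oa, ob, orf_a, orf_b = _ta_cassette(b.rng, spec, b.gc)
        if not _extends_upstream(seq, ob) and seq[ob:ob + 3] == "ATG":
            break
    else:
        raise ValidationError("could not place TA overlap without frame clash")
    base = b.emit(seq)
    sa, sb = base + oa, base + ob
    b.truth.append(TruthFeature("ta_orf_a", sa, sa + len(orf_a),
                                payload={"sequence": orf_a}))
    b.truth.append(TruthFeature("ta_orf_b", sb, sb + len(orf_b),
                                payload={"sequence": orf_b}))
    b.truth.append(TruthFeature("ta_pair", sa, sb + len(orf_b),
                                payload={"gap": spec.gap}))


def _build_par(b: _Builder, spec: ParSpec) -> None:
    rng = b.rng
    unit = _bases(rng, spec.parS_unit_len, b.gc)
    parts = []
    for k in range(spec.parS_units):
        if k:
            parts.append(_bases(rng, 3, b.gc))
        u = list(unit)
        if k:  # non-identical copies: one substitution each
            p = int(rng.integers(len(u)))
            u[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[u[p]]
        parts.append("".join(u))
    parS = "".join(parts)
    start = b.emit(parS)
    b.feature("parS", start, len(parS), n_units=spec.parS_units,
              unit_len=spec.parS_unit_len)
    b.pad(int(rng.integers(20, 40)))
    b.emit(_GUARD)
    override = {10 + k: _WALKER_A_CODONS[3 * k:3 * k + 3] for k in range(7)}
    parA = _orf_nt(rng, 120, b.gc, body_override=override)
    start = b.emit(parA)
    b.feature("parA_orf", start, len(parA), sequence=parA,
              walker_a=spec.walker_a)
    b.pad(8)
    b.emit(_GUARD)
    parB = _orf_nt(rng, 70, b.gc)
    start = b.emit(parB)
    b.feature("parB_orf", start, len(parB), sequence=parB)


def _build_islet(b: _Builder, spec: IsletSpec) -> None:
    rng = b.rng
    start = b.pos
    orf_codons = max(50, min(120, spec.length // (3 * (spec.n_orfs + 1) * 2)))
    outer_gc = b.gc
    b.gc = spec.gc  # the whole islet, genes included, sits at its own GC
    try:
        for _ in range(spec.n_orfs):
            b.emit(_bases(rng, 47, spec.gc) + _GUARD)
            orf = _orf_nt(rng, orf_codons, spec.gc)
            s = b.emit(orf)
            b.truth.append(TruthFeature("islet_orf", s, s + len(orf),
                                        payload={"sequence": orf}))
        remaining = spec.length - (b.pos - start)
        if remaining < 0:
            raise ValidationError("islet ORFs overflow the islet length")
        b.pad(remaining)
    finally:
        b.gc = outer_gc
    b.truth.append(TruthFeature("islet", start, start + spec.length,
                                payload={"gc": spec.gc}))


def _assemble(spec: PlasmidSpec, rng: np.random.Generator) -> tuple[str, list[TruthFeature]]:
    b = _Builder(rng, spec.background_gc)
    b.pad(int(rng.integers(150, 300)))
    if spec.rep:
        _build_rep(b, spec.rep)
        b.pad(int(rng.integers(100, 250)))
    if spec.mob:
        _build_mob(b, spec.mob)
        b.pad(int(rng.integers(100, 250)))
    if spec.ta:
        _build_ta(b, spec.ta)
        b.pad(int(rng.integers(100, 250)))
    if spec.par:
        _build_par(b, spec.par)
        b.pad(int(rng.integers(100, 250)))
    if spec.islet:
        _build_islet(b, spec.islet)
    if b.pos > spec.length:
        raise ValidationError(
            f"planted features need {b.pos} bp but length is {spec.length}; "
            f"overflow {b.pos - spec.length} bp")
    b.pad(spec.length - b.pos)
    return "".join(b.parts), b.truth


def _layout_ok(seq: str, truth: list[TruthFeature],
               min_codons: int = 40) -> bool:
    """Check the emitted layout against the annotator's ORF model.

    Accepts a draw only when every planted ORF survives primary ORF
    selection at its exact coordinates and no unplanned primary + strand
    ORF intrudes into a planted cassette.
    """
    n = len(seq)
    planted_orfs = {(f.start0, f.end0) for f in truth if "orf" in f.kind}
    rec = PlasmidRecord("_check", seq, "circular")
    prim = primary_orfs(find_orfs(rec, min_codons=min_codons), n)
    found = {o.span(n) for o in prim if o.strand == "+"}
    if not planted_orfs <= found:
        return False
    for orf in prim:
        if orf.strand != "+" or orf.span(n) in planted_orfs:
            continue
        # an unplanned short ORF operon-coupled (gap within the TA pairing
        # range) to a planted gene would shadow the planted pair structure
        if not (40 <= orf.length_codons <= 200):
            continue
        lo, hi = orf.span(n)
        for a, c in planted_orfs:
            if -20 <= lo - c <= 30 or -20 <= a - hi <= 30:
                return False
    return True


def generate_plasmid(spec: PlasmidSpec) -> tuple[PlasmidRecord, TruthRecord]:
    """Emit a synthetic circular plasmid and its ground truth.

    Deterministic in ``spec.seed``.  Draws creating unplanned long ORFs
    that overlap planted cassettes on the planted strand are rejected and
    redrawn (bounded retries, still seed-deterministic).
    """
    for attempt in range(60):
        rng = np.random.default_rng([spec.seed, attempt])
        seq, truth = _assemble(spec, rng)
        if _layout_ok(seq, truth):
            break
    record = PlasmidRecord(f"synthetic_seed{spec.seed}", seq, "circular")
    tr = TruthRecord(truth)
    tr.validate(seq)
    return record, tr


# ---------------------------------------------------------------------------
# Kimura two-parameter sequence evolution, for validating the tree stage
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _k2p_probs(d: float, ts_tv_ratio: float) -> np.ndarray:
    """4x4 substitution probability matrix after branch length d (subs/site)."""
    R = ts_tv_ratio
    beta = 1.0 / (2.0 * (R + 1.0))
    alpha = R / (R + 1.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_tv = 0.25 - 0.25 * e1          # each of the two transversion targets
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    M = np.full((4, 4), p_tv)
    for b, i in _BASE_INDEX.items():
        M[i, i] = p_same
        M[i, _BASE_INDEX[_TS_PARTNER[b]]] = p_ts
    return M


def generate_k2p_alignment(tree, seq_len: int, ts_tv_ratio: float = 2.0,
                           seed: int = 0) -> dict[str, str]:
    """Evolve sequences down a tree under the Kimura two-parameter model.

    ``tree`` is a scikit-bio TreeNode with branch lengths in expected
    substitutions per site; the root sequence is drawn uniformly.
    Returns {leaf name: sequence} — an ungapped multiple alignment.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_len)
    out: dict[str, str] = {}

    def descend(node, parent_seq):
        for child in node.children:
            d = child.length or 0.0
            if d < 0:
                raise ValidationError("negative branch length")
            if d == 0:
                child_seq = parent_seq.copy()
            else:
                M = _k2p_probs(d, ts_tv_ratio)
                cum = np.cumsum(M, axis=1)
                u = rng.random(seq_len)
                child_seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
            if child.is_tip():
                out[child.name] = "".join("ACGT"[i] for i in child_seq)
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return out
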