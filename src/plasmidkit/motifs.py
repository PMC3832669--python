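"""Degenerate consensus motif scanning and case-annotated consensus parsing.

Patterns are written the way plasmid-biology papers print them: plain
letters, IUPAC one-letter codes for nucleotides (N = any), and
``[X/Y/Z]`` for explicit per-position alternatives, e.g. the DnaA box
``TT[T/A]TNCACA`` or the deviant Walker A ``KGG[T/N/V]GK[T]``.  For
protein patterns letters are literal and X matches anything.

Case-annotated consensi follow the convention where uppercase positions
are conserved and lowercase positions are variable; aligned alternatives
are written ``a/c`` style, so two printed sequences collapse into one
string (variant 1 reads the first letter of every slot, variant 2 the
second).
"""

from __future__ import annotations

from dataclasses import dataclass

from plasmidkit.genome import ValidationError, reverse_complement

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifPattern:
    name: str
    pattern: str
    max_mismatch: int = 0
    molecule: str = "nucleotide"

    def __post_init__(self) -> None:
        self.slots = _parse_pattern(self.pattern, self.molecule)
        if not self.slots:
            raise ValidationError(f"{self.name}: empty pattern")

    def __len__(self) -> int:
        return len(self.slots)


@dataclass
class MotifHit:
    pattern_name: str
    start: int          # 1-based position of the first matched base/residue
    strand: str
    mismatches: int
    matched_sequence: str


def _parse_pattern(pattern: str, molecule: str) -> list[frozenset[str]]:
    """Expand a pattern string into per-position allowed-character sets."""
    slots: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            alts = [a.strip().upper() for a in pattern[i + 1:j].split("/")]
            if any(len(a) != 1 for a in alts):
                raise ValidationError(f"malformed alternative group in {pattern!r}")
            allowed: set[str] = set()
            for a in alts:
                allowed |= _char_set(a, molecule)
            slots.append(frozenset(allowed))
            i = j + 1
        elif ch.isalpha():
            slots.append(frozenset(_char_set(ch.upper(), molecule)))
            i += 1
        else:
            raise ValidationError(f"illegal character {ch!r} in pattern {pattern!r}")
    return slots


def _char_set(ch: str, molecule: str) -> set[str]:
    if molecule == "nucleotide":
        if ch not in IUPAC_SETS:
            raise ValidationError(f"not an IUPAC nucleotide code: {ch!r}")
        return set(IUPAC_SETS[ch])
    if ch == "X":
        return set(AA_ALPHABET)
    if ch not in AA_ALPHABET:
        raise ValidationError(f"not an amino-acid code: {ch!r}")
    return {ch}


def _matches(slot: frozenset[str], ch: str, molecule: str) -> bool:
    """IUPAC-vs-IUPAC: a position matches when the code sets intersect."""
    if molecule == "nucleotide":
        return bool(slot & set(IUPAC_SETS.get(ch, "")))
    return ch in slot or ch == "X"


def scan_motif(subject, pattern: MotifPattern,
               both_strands: bool | None = None) -> list[MotifHit]:
    """All pattern occurrences with <= max_mismatch mismatches.

    ``subject`` may be a PlasmidRecord, a nucleotide string or an
    amino-acid string; both strands are scanned for nucleotide patterns
    unless ``both_strands=False``.
    """
    seq = subject.sequence if hasattr(subject, "sequence") else str(subject).upper()
    nt = pattern.molecule == "nucleotide"
    if both_strands is None:
        both_strands = nt
    strands = [("+", seq)]
    if both_strands and nt:
        strands.append(("-", reverse_complement(seq)))
    m = len(pattern)
    hits: list[MotifHit] = []
    for strand, s in strands:
        n = len(s)
        for i in range(n - m + 1):
            mm = 0
            for k, slot in enumerate(pattern.slots):
                if not _matches(slot, s[i + k], pattern.molecule):
                    mm += 1
                    if mm > pattern.max_mismatch:
                        break
            else:
                start = i + 1 if strand == "+" else n - i - m + 1
                hits.append(MotifHit(pattern.name, start, strand, mm, s[i:i + m]))
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def parse_case_consensus(text: str) -> tuple[list[str], int]:
    """Expand a case-annotated consensus into variant sequences.

    Returns ``(variants, n_variable)`` where ``n_variable`` counts the
    lowercase (non-conserved) positions.  Slots written ``x/y`` carry the
    aligned alternatives of the printed variants; all such slots must
    have the same arity.
    """
    slots: list[list[str]] = []
    variable = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if not ch.isalpha():
            raise ValidationError(f"illegal character {ch!r} in consensus")
        if ch.isupper():
            slots.append([ch])
            i += 1
            continue
        # lowercase slot, possibly x/y/z alternatives
        alts = [ch.upper()]
        i += 1
        while i + 1 < len(text) + 1 and i < len(text) and text[i] == "/":
            if i + 1 >= len(text) or not text[i + 1].islower():
                raise ValidationError("dangling '/' in consensus")
            alts.append(text[i + 1].upper())
            i += 2
        variable += 1
        slots.append(alts)

    arities = {len(s) for s in slots if len(s) > 1}
    if len(arities) > 1:
        raise ValidationError(f"alternatives of unequal arity: {sorted(arities)}")
    n_variants = arities.pop() if arities else 1
    variants = []
    for v in range(n_variants):
        variants.append("".join(s[v] if len(s) > 1 else s[0] for s in slots))
    return variants, variable


# ---------------------------------------------------------------------------
# Built-in pattern library.  Editable: same columns can be supplied from a
# plain-text table via load_patterns(); names here are the ones the module
# annotator looks up.
# ---------------------------------------------------------------------------
BUILTIN_PATTERN_TABLE = """\
# name	molecule	pattern	max_mismatch
dnaA_box	nucleotide	TT[T/A]TNCACA	1
ihf_box_pMOS6	nucleotide	NAACNTCTGTCTTG	2
oriT_MOBQ	nucleotide	NWACCNNTAAGTGCGCCCTYNN	2
oriT_MOBP5	nucleotide	GGGGGATTGAAGGGGGCCANNNGCCCCCTCACAAGC	3
oriT_MOBQ3	nucleotide	ATAAGTGGGCACTTCGTGTCTTGCACCCTAN	2
oriT_MOBV	nucleotide	AATTTGGNCNNNNGNCAAATTGTCTAGTNAGTNNACATNNNNCTNNNNT	4
walker_A_deviant	protein	KGG[T/N/V]GK[T]	2
m5C_motif_IV	protein	PC	0
"""


def load_patterns(text: str) -> dict[str, MotifPattern]:
    patterns = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValidationError(f"pattern table row needs 4 columns: {line!r}")
        name, molecule, pat, mm = fields
        patterns[name] = MotifPattern(name=name, pattern=pat,
                                      max_mismatch=int(mm), molecule=molecule)
    return patterns


def builtin_patterns() -> dict[str, MotifPattern]:
    """The shipped pattern library (DnaA box, oriT consensi, Walker A...)."""
    return load_patterns(BUILTIN_PATTERN_TABLE)
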