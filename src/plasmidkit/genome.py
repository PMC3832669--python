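"""Sequence containers, ORF calling, translation and GC arithmetic.

Coordinate conventions
----------------------
Internally every interval is zero-based half-open.  Reported ORF
coordinates are 1-based inclusive GenBank style: ``start`` is the first
base of the start codon and ``end`` the last base of the stop codon, both
on the forward strand (so a minus-strand ORF has ``start > end`` unless it
wraps the origin).  Islet-style interval reports elsewhere in the package
follow the ``size = end - start`` rule instead; see :mod:`plasmidkit.islets`.

Circular replicons are first-class: ORFs may span the origin, and GC
windows wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger("plasmidkit")

IUPAC_NT = set("ACGTNRYSWKMBDHV")
AMBIGUOUS = IUPAC_NT - set("ACGT")
STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_MIN_CODONS = 40

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class ValidationError(ValueError):
    """Input violates a documented precondition."""


@dataclass
class Orf:
    """An open reading frame, start codon through stop codon inclusive.

    ``start``/``end`` are 1-based forward-strand positions of the first
    base of the start codon and the last base of the stop codon.  On the
    minus strand the start codon lies at the higher coordinate.
    """

    start: int
    end: int
    strand: str
    length_codons: int
    aa_sequence: str
    alt_starts: tuple[int, ...] = ()
    # zero-based half-open interval on the reading strand of the doubled
    # sequence; kept for internal arithmetic only
    _s0: int = 0
    _e0: int = 0

    @property
    def length_nt(self) -> int:
        return 3 * self.length_codons

    def span(self, seq_len: int) -> tuple[int, int]:
        """Forward-strand zero-based half-open footprint (lo, hi).

        ``hi`` may exceed ``seq_len`` when the ORF wraps the origin.
        """
        if self.strand == "+":
            lo = self.start - 1
        else:
            lo = self.end - 1
        hi = lo + self.length_nt
        return lo, hi

    def overlaps(self, lo: int, hi: int, seq_len: int) -> bool:
        a, b = self.span(seq_len)
        for shift in (0, -seq_len, seq_len):
            if a + shift < hi and lo < b + shift:
                return True
        return False


@dataclass
class PlasmidRecord:
    """A named (usually circular) replicon with accumulated annotations."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"{self.id}: topology must be circular or linear")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in IUPAC_NT:
                raise ValidationError(
                    f"{self.id}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def window(self, start0: int, end0: int) -> str:
        """Zero-based half-open slice with circular wrap."""
        n = len(self.sequence)
        if end0 - start0 > n:
            raise ValidationError("window longer than sequence")
        if end0 < start0:
            end0 += n
        length = end0 - start0
        start0 %= n
        stop = start0 + length
        if stop <= n:
            return self.sequence[start0:stop]
        if not self.is_circular:
            raise ValidationError("window wraps origin of a linear record")
        return self.sequence[start0:] + self.sequence[: stop - n]

    def rotate(self, k: int) -> "PlasmidRecord":
        """Rotate a circular record so old position k becomes position 0."""
        if not self.is_circular:
            raise ValidationError("cannot rotate a linear record")
        n = len(self.sequence)
        k %= n
        return PlasmidRecord(self.id, self.sequence[k:] + self.sequence[:k], "circular")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; full IUPAC alphabet accepted."""
    for pos, ch in enumerate(seq.upper(), start=1):
        if ch not in IUPAC_NT:
            raise ValidationError(f"non-IUPAC character {ch!r} at position {pos}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_sequences(
    path: str | Path,
    fmt: str | None = None,
    default_topology: str = "circular",
) -> list[PlasmidRecord]:
    """Read FASTA or GenBank flat files into :class:`PlasmidRecord` objects.

    Topology is taken from the GenBank LOCUS line when present, otherwise
    ``default_topology`` applies.  An empty file yields an empty list with
    a logged warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    records: list[PlasmidRecord] = []
    for rec in SeqIO.parse(str(path), fmt):
        topo = default_topology
        if fmt == "genbank":
            topo = rec.annotations.get("topology", default_topology)
        records.append(PlasmidRecord(rec.id, str(rec.seq), topo))
    if not records:
        log.warning("no sequences parsed from %s", path)
    return records


def gc_fraction_pct(seq: str) -> float:
    """GC percentage of a plain string; ambiguous bases excluded entirely."""
    gc = sum(1 for c in seq if c in "GC")
    denom = sum(1 for c in seq if c in "ACGT")
    if denom == 0:
        raise ValidationError("no unambiguous bases in window")
    return 100.0 * gc / denom


def gc_content(record: PlasmidRecord | str, start: int | None = None,
               end: int | None = None) -> float:
    """GC percentage of a record window.

    ``start``/``end`` follow the reporting rule size = end - start with a
    1-based start: the window covers 1-based bases ``start .. end-1``.
    Omitting both gives the whole record.  Circular wrap is allowed
    (``end`` past the length, or end < start).
    """
    if isinstance(record, str):
        record = PlasmidRecord("_anon", record, "linear")
    n = len(record)
    if start is None and end is None:
        return gc_fraction_pct(record.sequence)
    if start is None or end is None:
        raise ValidationError("give both start and end, or neither")
    if start < 1:
        raise ValidationError("start must be >= 1")
    s0 = start - 1
    e0 = end - 1
    if e0 <= s0 and not record.is_circular:
        raise ValidationError("empty or inverted window on a linear record")
    if e0 == s0:
        raise ValidationError("empty window")
    return gc_fraction_pct(record.window(s0, e0 if e0 > s0 else e0 + n))


_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def translate(nt: str | Orf, *, alt_start: bool = True) -> str:
    """Translate an ORF nucleotide sequence with the bacterial code.

    The trailing stop codon is stripped; with ``alt_start`` the first
    codon is rendered M whatever the start codon.  An internal stop raises
    :class:`ValidationError`.
    """
    if isinstance(nt, Orf):
        return nt.aa_sequence
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValidationError("ORF length is not a multiple of 3")
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValidationError(f"internal stop codon at codon {i + 1}")
        aa.append(str(Seq(codon).translate(table=11)))
    if aa and alt_start:
        aa[0] = "M"
    return "".join(aa)


def _orfs_on_strand(
    strand_seq: str,
    n: int,
    circular: bool,
    min_codons: int,
    start_codons: frozenset[str],
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Maximal ORFs on one reading strand.

    ``strand_seq`` is the sequence read 5'->3' on that strand, doubled
    when circular.  Returns zero-based half-open (s, e) with s < n, plus
    in-frame alternative starts, deduplicated modulo n.
    """
    out = {}
    scan = strand_seq
    for offset in range(3):
        starts: list[int] = []
        for i in range(offset, len(scan) - 2, 3):
            codon = scan[i:i + 3]
            if codon in STOP_CODONS:
                for s in starts:
                    e = i + 3
                    if s >= n:
                        continue
                    if e - s > n:  # cannot occupy more than the whole circle
                        continue
                    if (e - s) // 3 >= min_codons:
                        # one ORF per stop codon of the circle: keep the
                        # furthest-upstream (longest) start
                        key = e % n if circular else e
                        if key not in out or e - s > out[key][1] - out[key][0]:
                            alts = tuple(
                                a for a in starts if s < a < e and a % n != s
                            )
                            out[key] = (s, e, alts)
                    break  # only the longest (earliest) start per stop
                # remaining shorter starts become alternatives, recorded above
                starts = []
            elif codon in start_codons:
                starts.append(i)
    return sorted(out.values())


def find_orfs(
    record: PlasmidRecord,
    min_codons: int = DEFAULT_MIN_CODONS,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[Orf]:
    """All maximal ORFs on both strands, six frames, wrapping when circular.

    Within a frame the ORF reported for each stop codon runs from the
    furthest upstream start codon; nearer in-frame starts are listed as
    alternatives.  ORFs containing an ambiguous base are dropped with a
    warning.  Output order is (forward start position, strand).
    """
    if min_codons < 2:
        raise ValidationError("min_codons must be >= 2")
    start_codons = frozenset(s.upper() for s in start_codons)
    n = len(record)
    fwd = record.sequence * 2 if record.is_circular else record.sequence
    rev_full = reverse_complement(record.sequence)
    rev = rev_full * 2 if record.is_circular else rev_full

    orfs: list[Orf] = []
    for strand, strand_seq in (("+", fwd), ("-", rev)):
        for s, e, alts in _orfs_on_strand(strand_seq, n, record.is_circular,
                                          min_codons, start_codons):
            nt = strand_seq[s:e]
            if AMBIGUOUS & set(nt):
                log.warning("%s: dropping ORF with ambiguous bases at %d%s",
                            record.id, s, strand)
                continue
            try:
                aa = translate(nt)
            except ValidationError:
                continue
            if strand == "+":
                start = (s % n) + 1
                end = ((e - 1) % n) + 1
                alt_pos = tuple(sorted((a % n) + 1 for a in alts))
            else:
                start = n - (s % n)
                end = n - ((e - 1) % n)
                alt_pos = tuple(sorted(n - (a % n) for a in alts))
            orfs.append(Orf(start=start, end=end, strand=strand,
                            length_codons=(e - s) // 3, aa_sequence=aa,
                            alt_starts=alt_pos, _s0=s, _e0=e))
    orfs.sort(key=lambda o: (min(o.span(n)[0], n - 1), o.strand, o.end))
    return orfs


def primary_orfs(orfs: Sequence[Orf], seq_len: int,
                 max_shared: int = 30) -> list[Orf]:
    """Greedy non-nested ORF selection, longest first.

    Six-frame maximal ORF calling on GC-rich sequence reports many short
    ORFs nested in alternative frames of real genes.  This keeps the
    longest ORFs whose footprints share at most ``max_shared`` bp with
    any already-selected ORF — enough to retain genuinely overlapping
    operon pairs (toxin-antitoxin overlaps are a few bp) while dropping
    frame shadows.
    """
    chosen: list[Orf] = []
    for orf in sorted(orfs, key=lambda o: (-o.length_codons, o.start, o.strand)):
        lo, hi = orf.span(seq_len)
        ok = True
        for other in chosen:
            a, b = other.span(seq_len)
            shared = 0
            for shift in (0, -seq_len, seq_len):
                shared = max(shared, min(b + shift, hi) - max(a + shift, lo))
            if shared > max_shared:
                ok = False
                break
        if ok:
            chosen.append(orf)
    chosen.sort(key=lambda o: (o.span(seq_len)[0], o.strand))
    return chosen


def orf_nt(record: PlasmidRecord, orf: Orf) -> str:
    """Nucleotide sequence of an ORF, start through stop, reading strand."""
    n = len(record)
    lo, hi = orf.span(n)
    s = record.window(lo, hi)
    return s if orf.strand == "+" else reverse_complement(s)
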