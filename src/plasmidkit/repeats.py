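"""De-novo direct-repeat (iteron) arrays and inverted repeats.

Iterons — tandem direct repeats bound by the Rep initiator — and inverted
repeats around rep promoters are the structural signature of an
iteron-class plasmid replication origin.  Both finders here are exact,
deterministic, and defined precisely enough to be reproduced by a naive
O(n^2) scan, which the test suite does.

Semantics
---------
Direct repeats: a *seed pair* is two non-overlapping occurrences of a
common substring, extended to maximal length on both sides.  Seed pairs
with unit length >= ``min_unit`` and spacer in [0, ``max_spacer``] are
chained into arrays: starting from the pair, further units are appended
(and prepended) wherever a window within ``max_spacer`` of the previous
unit matches the running consensus with <= ``max_mismatch`` differences.
Overlapping arrays are resolved by (more units, longer unit, leftmost).

Inverted repeats: for every loop interval of length <= ``max_loop`` the
two arms are grown outward from the loop while the mismatch budget
holds; only the maximal arm per center is reported, and arms end on a
matching base pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from plasmidkit.genome import PlasmidRecord, ValidationError, reverse_complement

DEFAULT_MIN_UNIT = 15
DEFAULT_MAX_SPACER = 30
DEFAULT_MAX_MISMATCH = 1

DEFAULT_MIN_ARM = 8
DEFAULT_MAX_LOOP = 30
DEFAULT_IR_MISMATCH = 1

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RepeatArray:
    """A tandem array of direct repeats (an iteron candidate)."""

    unit_length: int
    units: list[tuple[int, int]]      # (1-based start, mismatches vs consensus)
    spacers: list[int]
    consensus: str
    strand: str = "+"

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def start(self) -> int:
        return self.units[0][0]

    @property
    def end(self) -> int:  # 1-based last base of last unit
        return self.units[-1][0] + self.unit_length - 1


@dataclass
class InvertedRepeat:
    left_arm: tuple[int, int]    # 1-based inclusive
    right_arm: tuple[int, int]
    arm_length: int
    loop: int
    mismatches: int


def _as_seq(record) -> str:
    return record.sequence if isinstance(record, PlasmidRecord) else str(record).upper()


def _region_seq(record, region: tuple[int, int] | None) -> tuple[str, int]:
    """Sub-sequence for a 1-based inclusive region, plus coordinate offset."""
    seq = _as_seq(record)
    if region is None:
        return seq, 0
    lo, hi = region
    if lo < 1 or hi > len(seq) or lo > hi:
        raise ValidationError(f"region {region} outside record of length {len(seq)}")
    return seq[lo - 1:hi], lo - 1


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _consensus(seqs: list[str]) -> str:
    out = []
    for col in zip(*seqs):
        counts = defaultdict(int)
        for c in col:
            counts[c] += 1
        out.append(max(sorted(counts), key=lambda c: counts[c]))
    return "".join(out)


def _seed_pairs(seq: str, min_unit: int, max_spacer: int) -> set[tuple[int, int, int]]:
    """Maximal non-overlapping repeat pairs (i, j, unit_len), 0-based.

    Found by exact k-mer seeding at k = min_unit; any repeated unit of
    length >= min_unit necessarily shares a k-mer, so this equals the
    all-substring-pairs scan.
    """
    n = len(seq)
    kmers: dict[str, list[int]] = defaultdict(list)
    for i in range(n - min_unit + 1):
        kmers[seq[i:i + min_unit]].append(i)
    pairs: set[tuple[int, int, int]] = set()
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                # extend left
                l = 0
                while i - l - 1 >= 0 and seq[i - l - 1] == seq[j - l - 1]:
                    l += 1
                a, b = i - l, j - l
                # extend right, units must not overlap
                u = min_unit + l
                while b + u < n and a + u < b and seq[a + u] == seq[b + u]:
                    u += 1
                u = min(u, b - a)  # clip overlap
                if u >= min_unit and 0 <= b - a - u <= max_spacer:
                    pairs.add((a, b, u))
    return pairs


def _chain(seq: str, a: int, b: int, u: int, max_spacer: int,
           max_mismatch: int) -> list[int]:
    """Grow a unit-position chain from a seed pair, consensus-guided."""
    positions = [a, b]
    consensus = seq[a:a + u]
    # forward
    while True:
        prev_end = positions[-1] + u
        found = None
        for c in range(prev_end, min(prev_end + max_spacer, len(seq) - u) + 1):
            if c + u <= len(seq) and _hamming(seq[c:c + u], consensus) <= max_mismatch:
                found = c
                break
        if found is None:
            break
        positions.append(found)
        consensus = _consensus([seq[p:p + u] for p in positions])
    # backward
    while True:
        first = positions[0]
        found = None
        for c in range(first - u, max(first - u - max_spacer, 0) - 1, -1):
            if c >= 0 and _hamming(seq[c:c + u], consensus) <= max_mismatch:
                found = c
                break
        if found is None:
            break
        positions.insert(0, found)
        consensus = _consensus([seq[p:p + u] for p in positions])
    return positions


def find_direct_repeats(
    record,
    region: tuple[int, int] | None = None,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_spacer: int = DEFAULT_MAX_SPACER,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[RepeatArray]:
    """Find maximal tandem direct-repeat arrays (iteron candidates)."""
    if min_unit < 8:
        raise ValidationError("min_unit must be >= 8")
    seq, offset = _region_seq(record, region)

    candidates: list[RepeatArray] = []
    seen: set[tuple[int, ...]] = set()
    for a, b, u in sorted(_seed_pairs(seq, min_unit, max_spacer)):
        positions = _chain(seq, a, b, u, max_spacer, max_mismatch)
        key = (u, *positions)
        if key in seen:
            continue
        seen.add(key)
        consensus = _consensus([seq[p:p + u] for p in positions])
        units = [(p + offset + 1, _hamming(seq[p:p + u], consensus))
                 for p in positions]
        spacers = [positions[k + 1] - (positions[k] + u)
                   for k in range(len(positions) - 1)]
        if any(m > max_mismatch for _, m in units):
            continue
        candidates.append(RepeatArray(unit_length=u, units=units,
                                      spacers=spacers, consensus=consensus))

    # resolve overlaps: prefer more units, then longer unit, then leftmost
    candidates.sort(key=lambda r: (-r.n_units, -r.unit_length, r.start))
    chosen: list[RepeatArray] = []
    for cand in candidates:
        clo, chi = cand.start, cand.end
        if all(chi < r.start or r.end < clo for r in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def find_inverted_repeats(
    record,
    region: tuple[int, int] | None = None,
    min_arm: int = DEFAULT_MIN_ARM,
    max_loop: int = DEFAULT_MAX_LOOP,
    max_mismatch: int = DEFAULT_IR_MISMATCH,
) -> list[InvertedRepeat]:
    """All maximal inverted repeats with arm >= min_arm, loop <= max_loop."""
    if min_arm < 4:
        raise ValidationError("min_arm must be >= 4")
    seq, offset = _region_seq(record, region)
    n = len(seq)
    results = []
    for loop in range(0, max_loop + 1):
        for left_end in range(1, n - loop):  # exclusive end of left arm
            right_start = left_end + loop
            # grow arms outward from the loop
            arm = 0
            mism = 0
            best = None
            while left_end - arm - 1 >= 0 and right_start + arm < n:
                x = seq[left_end - arm - 1]
                y = seq[right_start + arm]
                pair_mismatch = _COMP.get(x) != y
                if mism + pair_mismatch > max_mismatch:
                    break
                mism += pair_mismatch
                arm += 1
                if not pair_mismatch:
                    best = (arm, mism)  # arms must end on a matching pair
            if best and best[0] >= min_arm:
                arm, mism = best
                results.append(InvertedRepeat(
                    left_arm=(offset + left_end - arm + 1, offset + left_end),
                    right_arm=(offset + right_start + 1, offset + right_start + arm),
                    arm_length=arm, loop=loop, mismatches=mism))
    # drop IRs strictly contained in a longer IR at the same center
    results.sort(key=lambda r: (r.mismatches, -r.arm_length,
                                r.left_arm[0], r.loop))
    return results


def is_perfect_palindrome(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    if len(seq) % 2:
        return False
    return seq == reverse_complement(seq)
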