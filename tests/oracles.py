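"""Independent brute-force oracles used by the test suite.

Each oracle re-states the documented semantics of a finder in the most
naive way possible (all-pairs scans, exhaustive DP) so the optimized
implementations can be checked against them on small inputs.
"""

from __future__ import annotations

from collections import defaultdict

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def orf_oracle(seq: str, circular: bool, min_codons: int,
               start_codons=("ATG", "GTG", "TTG")) -> set[tuple[int, int, str]]:
    """All maximal ORFs as (start_1based, end_1based, strand) triples.

    Direct definition: for every strand and every position, read codons
    (wrapping once when circular) until a stop; keep ORFs >= min_codons
    whose start codon is the furthest upstream for its stop codon.
    """
    n = len(seq)
    found = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        text = s + s if circular else s
        limit = n if circular else len(s)
        # ORF = earliest start per (stop position mod n, frame)
        for start in range(limit):
            if text[start:start + 3] not in start_codons:
                continue
            pos = start
            while pos + 3 <= len(text) and pos + 3 - start <= n:
                codon = text[pos:pos + 3]
                if codon in STOPS:
                    break
                pos += 3
            else:
                continue
            if text[pos:pos + 3] not in STOPS:
                continue
            end = pos + 3
            if (end - start) // 3 < min_codons:
                continue
            key = (strand, end % n if circular else end)
            if key not in found or end - start > found[key][1] - found[key][0]:
                found[key] = (start, end)
    out = set()
    for (strand, _), (start, end) in found.items():
        if strand == "+":
            out.add(((start % n) + 1, ((end - 1) % n) + 1, "+"))
        else:
            out.add((n - (start % n), n - ((end - 1) % n), "-"))
    return out


def direct_repeat_pairs_oracle(seq: str, min_unit: int,
                               max_spacer: int) -> set[tuple[int, int, int]]:
    """All maximal non-overlapping exact repeat pairs by O(n^2) scan."""
    n = len(seq)
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j]:
                continue
            # maximal left extension
            if i > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal; counted at the shifted pair
            u = 0
            while j + u < n and i + u < j and seq[i + u] == seq[j + u]:
                u += 1
            u = min(u, j - i)
            if u >= min_unit and 0 <= j - i - u <= max_spacer:
                pairs.add((i, j, u))
    return pairs


def inverted_repeat_oracle(seq: str, min_arm: int, max_loop: int,
                           max_mismatch: int) -> set[tuple[int, int, int, int]]:
    """All maximal IRs as (left_end_excl, loop, arm, mismatches), 0-based.

    For every loop placement, grow arms outward while the mismatch budget
    holds; arms end on a matching pair.
    """
    n = len(seq)
    out = set()
    for loop in range(max_loop + 1):
        for left_end in range(1, n - loop):
            right_start = left_end + loop
            arm = mism = 0
            best = None
            while left_end - arm - 1 >= 0 and right_start + arm < n:
                x, y = seq[left_end - arm - 1], seq[right_start + arm]
                bad = _COMP.get(x) != y
                if mism + bad > max_mismatch:
                    break
                mism += bad
                arm += 1
                if not bad:
                    best = (arm, mism)
            if best and best[0] >= min_arm:
                out.add((left_end, loop, best[0], best[1]))
    return out


def nw_score_oracle(a: str, b: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Gotoh affine-gap global alignment score by exhaustive DP."""
    inf = float("-inf")
    la, lb = len(a), len(b)
    M = [[inf] * (lb + 1) for _ in range(la + 1)]
    X = [[inf] * (lb + 1) for _ in range(la + 1)]  # gap in b (a consumed)
    Y = [[inf] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0 and j > 0:
                s = score_fn(a[i - 1], b[j - 1])
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(X[i - 1][j] + gap_extend,
                              M[i - 1][j] + gap_open,
                              Y[i - 1][j] + gap_open)
            if j > 0:
                Y[i][j] = max(Y[i][j - 1] + gap_extend,
                              M[i][j - 1] + gap_open,
                              X[i][j - 1] + gap_open)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def translate_oracle(nt: str) -> str:
    """Codon-table lookup translation, bacterial code, first aa forced M."""
    table = {}
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
           "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
    k = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[k]
                k += 1
    codons = [nt[i:i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
    if codons and codons[-1] in STOPS:
        codons.pop()
    aa = "".join(table[c] for c in codons)
    return ("M" + aa[1:]) if aa else aa
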