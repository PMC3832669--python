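"""Windowed GC profiling and plasmid-islet detection.

A plasmid islet (PI) is a contiguous, typically horizontally-acquired
region whose GC content sits well below the replicon average.  Detection
is purely compositional: a sliding-window GC profile is thresholded at
``background - delta`` percentage points, runs of depressed windows are
merged and refined to base resolution, and the background is recomputed
once excluding the detected islets (the "remaining part of the plasmid").

Reported islet intervals follow the size = end - start rule: the interval
(start, end) covers 1-based bases start .. end-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plasmidkit.genome import PlasmidRecord, ValidationError, gc_fraction_pct

DEFAULT_WINDOW = 200
DEFAULT_STEP = 50
DEFAULT_DELTA = 5.0
DEFAULT_MIN_LEN = 500
DEFAULT_MERGE_GAP = 200


@dataclass
class GCProfile:
    window: int
    step: int
    values: list[tuple[int, float]]  # (1-based window start, GC %)
    background_gc: float
    seq_len: int
    circular: bool


@dataclass
class GCIslet:
    start: int          # 1-based; islet covers bases start .. end-1
    end: int
    islet_gc: float
    background_gc: float  # GC of the remaining part of the plasmid
    contained_orfs: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start


def _gc_flags(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    return is_gc.astype(np.int64), (is_gc | is_at).astype(np.int64)


def gc_profile(record: PlasmidRecord, window: int = DEFAULT_WINDOW,
               step: int = DEFAULT_STEP) -> GCProfile:
    """GC percentage per sliding window, wrapping when circular."""
    n = len(record)
    if window < 20:
        raise ValidationError("window must be >= 20 bp")
    if step > window:
        raise ValidationError("step must be <= window")
    if window > n:
        raise ValidationError("window longer than sequence")
    gc, ok = _gc_flags(record.sequence)
    if record.is_circular:
        gc2 = np.concatenate([gc, gc])
        ok2 = np.concatenate([ok, ok])
        starts = np.arange(0, n, step)
    else:
        gc2, ok2 = gc, ok
        starts = np.arange(0, n - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(gc2)])
    co = np.concatenate([[0], np.cumsum(ok2)])
    values = []
    for s in starts:
        g = cg[s + window] - cg[s]
        d = co[s + window] - co[s]
        values.append((int(s) + 1, 100.0 * g / d if d else float("nan")))
    return GCProfile(window=window, step=step, values=values,
                     background_gc=gc_fraction_pct(record.sequence),
                     seq_len=n, circular=record.is_circular)


def _runs_below(profile: GCProfile, threshold: float,
                merge_gap: int) -> list[tuple[int, int]]:
    """Merged zero-based half-open bp intervals of depressed windows."""
    win, n = profile.window, profile.seq_len
    flagged = [(s - 1, s - 1 + win) for s, gc in profile.values
               if not np.isnan(gc) and gc <= threshold]
    if not flagged:
        return []
    merged: list[list[int]] = []
    for lo, hi in flagged:
        if merged and lo - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    # circular: a run touching the end may continue from position 0
    if profile.circular and len(merged) > 1:
        first, last = merged[0], merged[-1]
        if (first[0] + n) - last[1] <= merge_gap:
            last[1] = first[1] + n
            merged.pop(0)
    return [(lo, min(hi, lo + n)) for lo, hi in merged]


def _refine(seq_gc: np.ndarray, seq_ok: np.ndarray, lo: int, hi: int,
            threshold: float, window: int, n: int,
            circular: bool) -> tuple[int, int]:
    """Base-resolution boundary refinement.

    Within the run grown by one window on each side, the islet becomes
    the contiguous segment maximizing the AT-excess score
    ``sum(threshold/100 - is_gc)``: bases below the depression threshold
    extend it, bases above shrink it, so boundaries land exactly where
    the depression criterion stops holding.  Ties break toward the
    shorter, then leftmost, segment; edges therefore never end on G/C.
    """
    a = lo - window
    b = hi + window
    if not circular:
        a, b = max(a, 0), min(b, n)
    idx = np.arange(a, b) % n if circular else np.arange(a, b)
    score = np.where(seq_ok[idx] > 0, threshold / 100.0 - seq_gc[idx], 0.0)
    best_sum = 0.0
    best = (0, 0)
    cur = 0.0
    cur_start = 0
    for k, s in enumerate(score):
        if cur <= 0:
            cur = s
            cur_start = k
        else:
            cur += s
        if cur > best_sum + 1e-12 or (
                abs(cur - best_sum) <= 1e-12
                and (k + 1 - cur_start) < (best[1] - best[0])):
            best_sum = cur
            best = (cur_start, k + 1)
    if best_sum <= 0:
        return lo, hi
    lo_k, hi_k = a + best[0], a + best[1]

    # a weakly-depressed islet edge inside the window-qualified run should
    # not be double-trimmed: grow back to the run edge when the trimmed
    # stretch still satisfies the depression criterion on average (a
    # clearly-background stretch annexed by window merging stays out)
    def mean_gc(x, y):
        if y <= x:
            return float("inf")
        sel = idx[(x - a):(y - a)]
        d = seq_ok[sel].sum()
        return 100.0 * seq_gc[sel].sum() / d if d else float("inf")

    if lo < lo_k and mean_gc(lo, lo_k) <= threshold:
        lo_k = lo
    if hi > hi_k and mean_gc(hi_k, hi) <= threshold:
        hi_k = hi
    return lo_k, hi_k


def detect_islets(profile: GCProfile, record: PlasmidRecord,
                  delta: float = DEFAULT_DELTA,
                  min_len: int = DEFAULT_MIN_LEN,
                  merge_gap: int = DEFAULT_MERGE_GAP) -> list[GCIslet]:
    """Detect low-GC islets from a profile.

    Windows at or below ``background - delta`` are merged into candidate
    runs; after one pass the background is recomputed excluding the
    candidates and the threshold re-applied, so a large islet does not
    drag the background down and mask itself.  Reported ``background_gc``
    per islet is the GC of the plasmid excluding that islet.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    n = profile.seq_len
    seq_gc, seq_ok = _gc_flags(record.sequence)

    def remainder_gc(excl: list[tuple[int, int]]) -> float:
        mask = np.ones(n, dtype=bool)
        for lo, hi in excl:
            idx = np.arange(lo, hi) % n
            mask[idx] = False
        g = int(seq_gc[mask].sum())
        d = int(seq_ok[mask].sum())
        return 100.0 * g / d if d else float("nan")

    # pass 1: whole-record background locates candidate runs
    threshold = profile.background_gc - delta
    runs = _runs_below(profile, threshold, merge_gap)
    intervals = []
    for lo, hi in runs:
        lo, hi = _refine(seq_gc, seq_ok, lo, hi, threshold, profile.window,
                         n, profile.circular)
        if hi - lo >= min_len:
            intervals.append((lo, hi))
    if not intervals:
        return []
    # pass 2: re-refine boundaries against the background computed from
    # the remaining part of the plasmid (a large islet otherwise drags
    # the background down and truncates itself).  The boundary threshold
    # is the midpoint between islet and background GC — the natural
    # decision boundary between the two compositions — so locally
    # AT-leaning background does not get annexed.
    bg = remainder_gc(intervals)
    refined = []
    for lo, hi in intervals:
        idx = np.arange(lo, hi) % n
        g = int(seq_gc[idx].sum())
        d = int(seq_ok[idx].sum())
        islet_gc = 100.0 * g / d if d else bg
        threshold = min(0.5 * (islet_gc + bg), bg - delta)
        lo, hi = _refine(seq_gc, seq_ok, lo, hi, threshold, profile.window,
                         n, profile.circular)
        if hi - lo >= min_len:
            refined.append((lo, hi))
    intervals = refined
    if not intervals:
        return []

    islets = []
    for lo, hi in sorted(intervals):
        idx = np.arange(lo, hi) % n
        g = int(seq_gc[idx].sum())
        d = int(seq_ok[idx].sum())
        islet_gc = 100.0 * g / d
        rest = remainder_gc([(lo, hi)])
        if islet_gc > rest - delta:
            continue  # merged weak dips, not a genuine islet
        islets.append(GCIslet(start=lo + 1, end=lo + 1 + (hi - lo),
                              islet_gc=round(islet_gc, 1),
                              background_gc=round(rest, 1)))
    return islets


def assign_orfs(islets: list[GCIslet], orfs, seq_len: int) -> None:
    """Attach ORFs whose footprint lies mostly (>50%) inside an islet."""
    for islet in islets:
        lo, hi = islet.start - 1, islet.end - 1
        for orf in orfs:
            a, b = orf.span(seq_len)
            best = 0
            for shift in (0, -seq_len, seq_len):
                ov = min(b + shift, hi) - max(a + shift, lo)
                best = max(best, ov)
            if best > (b - a) / 2:
                islet.contained_orfs.append(orf)
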