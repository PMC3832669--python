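# Methods

This note records the models, conventions, parameter choices and known
limitations behind `plasmidkit`. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates

Internally every interval is zero-based half-open. Two reporting
conventions coexist, deliberately:

* **ORFs** are GenBank-style 1-based inclusive: `start` is the first
  base of the start codon, `end` the last base of the stop codon, both
  on the forward strand (a minus-strand ORF therefore has
  `start > end` unless it wraps the origin).
* **Islet-style intervals** follow the `size = end − start` rule: an
  interval `(start, end)` covers 1-based bases `start … end−1`. This
  matches the arithmetic of published plasmid-islet tables, where every
  printed size equals `end − start`.

Circular replicons are first-class: ORFs may span the origin (reported
with coordinates that wrap), GC windows tile the circle, and upstream
windows for oriV/oriT prediction wrap.

## ORF calling

All maximal ORFs on both strands and all six frames, computed on the
doubled sequence for circular records. One ORF is reported per stop
codon of the circle — the one with the furthest-upstream start codon;
nearer in-frame starts are kept as alternatives. Defaults: start codons
{ATG, GTG, TTG}, minimum 40 codons (antitoxins are short; typical small-
plasmid proteins start near 90 aa). ORFs containing ambiguous bases are
dropped with a warning. Alternative starts GTG/TTG translate to M
(bacterial code, translation table 11).

Six-frame maximal ORF calling on GC-rich DNA reports many frame shadows
nested inside real genes, so annotation runs on a **primary set**:
greedy selection longest-first, keeping ORFs that share at most 30 bp
with any already-selected ORF. The 30 bp allowance retains genuinely
overlapping operon pairs (toxin–antitoxin overlaps are a few bp) while
dropping nested frames. Real annotation pipelines resolve the same
ambiguity with coding statistics; a length-greedy rule is the
appropriate analogue for sequence with no codon-usage signal.

## GC profile and islet detection

Windows of 200 bp at 50 bp steps (defaults; window ≥ 20, step ≤ window
enforced) with circular wrap; ambiguous bases are excluded from both
numerator and denominator. Islet detection:

1. Windows with GC ≤ background − δ (δ = 5 points) are merged into
   runs; runs separated by ≤ 200 bp merge; runs shorter than 500 bp are
   discarded. Defaults were chosen so that islets like those in small
   *Paracoccus* plasmids (1.1–2.7 kb, depressed 10–19 points) sit
   comfortably inside the detectable regime.
2. The background is recomputed excluding the candidate islets (one
   refinement pass) — otherwise a large islet drags the average down
   and masks itself — and per-islet reports use the GC of the plasmid
   *excluding that islet* ("remaining part").
3. Boundaries are refined to base resolution as the contiguous segment
   maximizing the AT-excess score `Σ (t/100 − 1{GC})` within the run
   grown by one window on each side, where the refinement threshold `t`
   is the midpoint of islet and background GC — the natural decision
   boundary between the two compositions. Ties break toward the
   shorter, then leftmost, segment, so edges never end on G/C. A
   trimmed edge stretch is grown back to the window-run edge only if it
   still satisfies the depression criterion on average; this stops both
   double-trimming of weakly depressed islet edges and annexation of
   ordinary background bridged in by window merging.
4. Any candidate whose overall GC exceeds `background − δ` is dropped:
   every reported islet satisfies the depression invariant directly.

Detection is GC-only by design; k-mer composition and codon-usage
methods are out of scope.

## Repeats and motifs

**Direct repeats (iterons).** Exact k-mer seeding at k = `min_unit`
(default 15 bp) finds every repeated unit of that length or more; seed
pairs are extended to maximal length on both sides (units may not
overlap), kept when the spacer is 0–30 bp, and chained into arrays by
scanning outward for further units within `max_spacer` of the previous
one at ≤ 1 mismatch against the running majority-rule consensus.
Overlapping arrays resolve by (more units, longer unit, leftmost).
Because any repeated unit ≥ k shares an exact k-mer, the seeding layer
is provably equivalent to the all-substring-pairs O(n²) scan, and the
test suite asserts that equivalence against an independent brute-force
oracle. Maximal extension has one consequence worth knowing: if two
unit occurrences share the base flanking a boundary, that base is
absorbed into the unit — a 19 bp unit with colliding 2 bp spacers is
correctly reported as 20 bp with 1 bp spacers.

**Inverted repeats.** For every loop placement (loop ≤ 30 bp) arms grow
outward while the mismatch budget (default 1) holds; arms end on a
matching pair and only the maximal arm per center is reported. A
perfect palindrome is exactly a full-length IR with loop 0 and no
mismatches, and the finder satisfies that equivalence by test.

**Motif patterns** are written as papers print them: IUPAC codes
(N = any), `[X/Y/Z]` alternatives; for proteins, letters are literal and
X is a wildcard. IUPAC-vs-IUPAC positions match when the code sets
intersect. The shipped library carries the DnaA box `TT[T/A]TNCACA`,
an IHF-like box, the MOB_Q / MOB_Q3 / MOB_P5 / MOB_V oriT consensi, the
deviant Walker A `KGG[T/N/V]GK[T]`, and the m5C-MTase Pro-Cys catalytic
dipeptide; users can load additional patterns from a four-column
tab-separated table (name, molecule, pattern, max_mismatch).

**Case-annotated consensi** ("lowercase = non-conserved", `a/c` slots)
expand into aligned variants: variant *i* reads the *i*-th letter of
every slash group; single lowercase letters are non-conserved but
constant across variants; groups of unequal arity are an error.

## Module assembly

Rule-based, purely structural, with precedence
REP > MOB > PAR > TA > RM > ACCESSORY on conflicts (logged); every ORF
lands in exactly one module.

* **REP**: best-scoring ORF whose upstream 600 bp window shows an
  origin signature. Scored criteria: iteron array (≥ 2 units), inverted
  repeat, DnaA box, IHF box, partial inverted iteron within 60 bp of
  the start codon (reverse complement of the array consensus, truncated
  to ≥ 60 % of unit length — threshold invented and flagged in output).
  A REP call is *accepted* only when anchored on an iteron array or an
  IR with arm ≥ 14 bp: short IRs and single degenerate host-factor
  boxes arise freely in random sequence, and iteron-less replicons are
  exactly the ones with long IRs.
* **MOB**: ORF with an oriT consensus hit in its upstream 500 bp.
  Each oriT site is assigned to the single nearest downstream ORF
  (fewest mismatches, then closest) — otherwise every ORF within the
  window of one site would be called a relaxase gene. Without a
  user-supplied relaxase reference panel, MOB calls rest on oriT hits
  alone.
* **TA**: same-strand adjacent ORF pairs, both 40–200 codons, signed
  gap in [−20, +30] bp (bracketing observed 1 bp and 4 bp overlaps and
  10 bp intergenic architectures); claimed tightest-coupling first
  (smallest |gap|), since genuine TA operons overlap or nearly touch.
* **PAR**: a deviant-Walker-A ATPase adjacent to a short ORF with a
  parS-like array (≥ 3 units of 10–16 bp) upstream.
* **RM**: an adjacent ORF pair in which one product (≥ 200 codons)
  carries the Pro-Cys dipeptide hit; full m5C motif-order analysis is
  out of scope (database-driven).
* Everything else is ACCESSORY; ORFs lying mostly (> 50 %) inside a
  detected islet carry the PI flag.

## Comparison stage

Global alignment uses Needleman–Wunsch via `Bio.Align.PairwiseAligner`:
nucleotide match +1 / mismatch −1 / gap −2 (linear); protein BLOSUM62
with gap open −10 / extend −1. The aa scoring layer is verified against
an independent Gotoh DP oracle in the tests. Percent identity counts
identical columns over **all** alignment columns by default (gap
columns included); the denominator is configurable because this choice
alone shifts identities by several points, and it is not generally
knowable which convention a published identity used — hence published
identities are reproduced to ±1 point, not exactly.

K2P distances exclude gap/ambiguous columns pairwise and error on
saturation (log-domain violation). Neighbor joining is the standard
Saitou–Nei agglomeration with deterministic tie-breaking by smallest
index pair and negative branch lengths clamped to zero (logged); it is
exact on additive matrices (property-tested on random trees and
cross-checked once against scikit-bio's implementation). Bootstrap
resamples alignment columns with replacement, recomputes K2P + NJ per
replicate, and labels each internal node of the point-estimate tree
with the percentage of replicates containing its bipartition.
Ortholog pairing is reciprocal-best global aa identity ≥ 60 %.

## Synthetic plasmids

The generator emits the study conditions as its defaults: a 6 kb
circular replicon, backbone GC 0.60, a rep gene (150 codons) behind a
3 × 19 bp iteron array with 2 bp spacers and a DnaA box, a mob gene
(120 codons) behind an exact MOB_Q oriT expansion, a TA pair of two
90-codon ORFs overlapping 4 bp, and a 2 kb islet at GC 0.40 carrying
its own genes. All randomness flows from one integer seed through a
single stream; identical spec + seed gives byte-identical output.

Design choices that matter:

* **Gene-dense backbone.** Long inter-cassette stretches are packed
  with accessory filler genes separated by 50–90 bp gaps, as in real
  plasmids. A purely random background at GC 0.60 is stop-poor and
  breeds spurious ORFs that pair into fake operons.
* **Shadow-frame suppression.** Codons for planted genes are sampled
  base-wise at the target GC but rejected if they create a start codon
  in any of the five shadow frames (forward ATG/GTG/TTG at shifted
  offsets; CAT/CAC/CAA, the reverse-strand starts, anywhere). Each gene
  additionally carries fixed "stop-wall" blocks of sense codons near
  its ends whose shifted-frame trigrams are stops (TAG at offsets 1–2
  after the start; CTA, the reverse-complemented stop, at all three
  offsets before the stop), so spurious frames entering from a flank
  terminate within a few codons. Real genes owe the same property to
  codon bias; the walls are its minimal synthetic substitute. An
  in-frame TAA guard immediately upstream of each gene pins the
  reported start codon to the planted one.
* **Unambiguous iteron boundaries.** The bases flanking each iteron
  occurrence are made pairwise distinct (possible for up to four
  occurrences), so maximal extension cannot shift the unit boundary.
* **Calibration.** Rejection sampling discards AT-rich codons and
  would raise realized GC; the proposal GC is lowered by 0.02 so that
  whole-record GC is unbiased (checked to ±2 points at ≥ 3 kb).
* **Layout rejection.** A draw is discarded (bounded, seed-deterministic
  retries) unless every planted gene survives primary ORF selection at
  its exact coordinates and no unplanned short ORF sits within TA
  pairing distance of a planted gene.

TA overlaps of −1 and −4 bp are constructed exactly (the −4 layout is
the classic `…A·TGA` start-in-stop arrangement); other negative gaps
are not supported.

What the generator does **not** emulate: codon usage and amino-acid
composition of real proteins, insertion sequences and transposons,
promoters/RBS, replication-strand skew, and restriction-site avoidance.
Passing round-trip tests therefore demonstrates that the detectors
recover the *structural* signatures they target at realistic GC and
size scales — not that they match database-driven annotation of real
plasmids gene-for-gene.

K2P sequence evolution uses the exact closed-form transition matrix
parameterized by branch length (substitutions/site) and the
transition/transversion ratio R = P/Q (default 2; the rate matrix is
normalized to unit total rate), with a uniform root.

## Problem sizes and stochastic margins

The test suite and acceptance script use 6 kb plasmids, 20 round-trip
seeds, 50-input oracle sweeps on 200–600 bp sequences, 20 random
additive matrices (5–8 taxa), 2 kb simulated alignments and 100
bootstrap replicates; the CLI default for bootstrap is 1000 replicates.
Round-trip recall of planted REP/MOB/TA modules and islets is 100 %
across the tested seeds with at most one false extra module per
plasmid. Because islet bases are drawn independently, an islet edge
occasionally (≈ 1 % of plasmids) realizes at near-background GC over
its first couple hundred bases; no compositional detector can place
that boundary, so islet recall under fresh seeds is ≈ 99 % rather than
exactly 1.

## Known limitations

* REP/MOB calls without a reference panel rest entirely on cis
  signatures; relaxase- or Rep-family assignment by homology is out of
  scope.
* Motif hits carry mismatch counts, not statistical significance.
* The repeat finders are O(n·occurrences) and meant for replicons of
  tens of kb, not chromosomes.
* Identity percentages depend on the alignment scoring and denominator
  convention; both are configurable but the defaults are one choice
  among several defensible ones.
* The 16S-style tree stage is validated on simulated alignments; the
  package does not construct multiple sequence alignments (supply a
  pre-aligned FASTA).
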