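# plasmidkit

Structural annotation and comparison of small bacterial plasmid genomes
(roughly 3–15 kb mobilizable replicons), of the kind carried by
*Paracoccus* and other *Alphaproteobacteria*.

Small plasmids are mosaics of a few backbone cassettes — replication
(REP), mobilization (MOB), toxin–antitoxin stabilization (TA),
partitioning (PAR) — plus horizontally acquired "islets" of depressed GC
content. None of these need a reference database to find: each has a
*cis*-structural signature readable straight off the sequence.
`plasmidkit` predicts them all from a FASTA/GenBank file and compares
plasmids by alignment identity and distance-based phylogenetics:

* **oriV prediction** — tandem direct-repeat (iteron) arrays found *de
  novo* (exact seeding, maximal extension, consensus chaining), inverted
  repeats, DnaA-box hits against the consensus `TT[T/A]TNCACA`, IHF-like
  boxes, and partial inverted iterons next to the *rep* start codon.
* **oriT prediction** — degenerate consensus scanning upstream of
  candidate relaxase genes, with the MOB<sub>Q</sub> family consensus
  `NWACCNNTAAGTGCGCCCTYNN` and MOB<sub>P5</sub>/MOB<sub>V</sub> patterns
  shipped in an editable pattern library. Case-annotated consensi
  ("lowercase = non-conserved, `a/c` = aligned alternatives") are parsed
  natively.
* **TA operons** — pairs of short same-strand ORFs that overlap by a few
  bases or sit a short intergenic gap apart.
* **Plasmid islets (PI)** — sliding-window GC profiling, thresholding at
  `background − δ` percentage points, and base-resolution boundary
  refinement; the background is recomputed from the remaining part of
  the plasmid.
* **Comparison** — Needleman–Wunsch global identity, Kimura
  two-parameter distances
  `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`
  (P transitions/site, Q transversions/site), Saitou–Nei
  neighbor-joining, and nonparametric bootstrap supports.
* **Simulation** — a generator that emits circular plasmids with
  planted, exactly ground-truthed cassettes and islets, used as the test
  substrate for everything above, plus K2P sequence evolution along a
  tree for validating the phylogenetic stage.

## Worked example

Simulate a 6 kb plasmid (backbone GC 60 %) carrying a rep gene behind a
3 × 19 bp iteron array and a DnaA box, a mob gene behind an exact
MOB<sub>Q</sub> oriT, a TA pair with a 4 bp overlap, and a 2 kb islet at
GC 40 % — then annotate it blind:

```sh
plasmidkit simulate -o sim --seed 1
plasmidkit annotate sim/synthetic_seed1.fasta -o anno
cat anno/summary.tsv anno/islets.tsv
```

```
plasmid          size_bp  gc_pct  n_orfs  modules
synthetic_seed1  6000     53.3    14      REP, MOB, TA

plasmid          pi_size_bp  position   pi_gc  remaining_gc  orf_aa
synthetic_seed1  2006        2370-4376  40.8   59.5          119,131,195,70
```

The summary row is read like a characterization table: replicon size,
overall GC, ORF count, and the backbone module complement. The islet
row gives the PI size, its interval (the interval covers bases
`start..end−1`, so size = end − start), the islet's own GC, the GC of
the rest of the plasmid, and the lengths (aa) of the proteins it
encodes. The GFF3 in `anno/` places each prediction; here the oriT was
recovered at 1003–1024, exactly where the generator planted it, and the
predicted oriV region upstream of *rep* wraps the origin
(`rep_origin 5731 6330`, circular convention).

Compare plasmids or build a tree from a pre-aligned FASTA:

```sh
plasmidkit compare --aligned-fasta aln.fasta -o cmp --bootstrap 1000 --seed 13
cat cmp/nj_tree.nwk
```

```
(E:0.325,(C:0.046,D:0.049)100:0.325,(A:0.049,B:0.054)100:0.295);
```

— an unrooted NJ tree with bootstrap percentages as internal node
labels (here both splits of a 5-taxon K2P simulation at 100 %, branch
lengths in substitutions/site, truth 0.05/0.30).

As a library:

```python
import plasmidkit as pk

pk.is_perfect_palindrome("AGCCTTGCAAGGCT")        # True
lib = pk.builtin_patterns()
pk.scan_motif("TCATCCACA", lib["dnaA_box"])[0].mismatches   # 1
pk.parse_case_consensus("ATAAGTGGGCACTTCGTGTCTTGCACCCTAt/c")
# (['...TAT', '...TAC'], 1)  — two variants, one variable position
pk.k2p_distance("A"*100, "G"*10 + "C"*5 + "A"*85).d          # 0.170181
```

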