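#!/usr/bin/env python
"""Validate plasmidkit against the deposited Paracoccus plasmid records.

The 14 small Paracoccus spp. plasmids this package's methods were
exercised on are public GenBank records.  Download them (any mix of
GenBank flat files or FASTA, named <accession>.* or <plasmid>.*) into a
directory, e.g.:

    for acc in JQ041633 KC542384 JQ684024 JQ796370 JQ066766 JQ684023; do
        efetch -db nuccore -id $acc -format gb > tests/data/accessions/$acc.gb
    done

then run:

    python scripts/validate_accessions.py --data-dir tests/data/accessions

Checks performed (published values in parentheses):
  * record lengths and GC: pAES1 JQ041633 (2925 bp), pMARC1 KC542384
    (5122 bp, GC 49.0%)
  * pMARC1 islet window (1312, 3143) GC = 35.7%
  * five 19-bp direct repeats with 3-bp spacers upstream of the pHAE2
    (JQ684024) rep gene
  * pMARC1/pMOS7 (JQ684023) Rep amino-acid identity 96 +- 1
  * pAES3 (JQ066766) / pAES7 (JQ796370) TA-module nucleotide identity
    94 +- 1
  * a 28-bp-arm inverted repeat with 5 mismatches in the pAES1 oriV
"""

from __future__ import annotations

import argparse
import sys
from dataclasses import dataclass
from pathlib import Path

ACCESSIONS = {
    "pAES1": "JQ041633", "pAES2": "JQ065021", "pAES3": "JQ066766",
    "pAES4": "JQ684025", "pAES7": "JQ796370", "pHAE1": "JQ066767",
    "pHAE2": "JQ684024", "pMARC1": "KC542384", "pMARC2": "KC561053",
    "pMARC3": "KC561054", "pMARC4": "KC561055", "pMOS2": "JQ664550",
    "pMOS6": "JQ678602", "pMOS7": "JQ684023",
}

EXPECTED_LENGTHS = {"pAES1": 2925, "pMARC1": 5122, "pAES7": 13005}
EXPECTED_GC = {"pMARC1": 49.0, "pAES1": 64.4, "pAES7": 60.1}


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str


def load_records(data_dir: Path) -> dict:
    from plasmidkit.genome import read_sequences
    by_name: dict[str, object] = {}
    rev = {v: k for k, v in ACCESSIONS.items()}
    for path in sorted(data_dir.iterdir()):
        if path.suffix.lower() not in (".gb", ".gbk", ".genbank", ".fa",
                                       ".fasta"):
            continue
        for rec in read_sequences(path):
            stem = path.stem.split(".")[0]
            name = rev.get(stem, stem)
            if name not in ACCESSIONS:
                acc = rec.id.split(".")[0]
                name = rev.get(acc, rec.id)
            by_name[name] = rec
    return by_name


def run_checks(data_dir: Path) -> list[CheckResult]:
    import plasmidkit as pk
    from plasmidkit.genome import find_orfs, orf_nt, primary_orfs

    records = load_records(Path(data_dir))
    results: list[CheckResult] = []

    def check(name: str, cond: bool, detail: str) -> None:
        results.append(CheckResult(name, bool(cond), detail))

    for plasmid, want in EXPECTED_LENGTHS.items():
        if plasmid in records:
            got = len(records[plasmid])
            check(f"{plasmid}_length", got == want, f"{got} vs {want}")
    for plasmid, want in EXPECTED_GC.items():
        if plasmid in records:
            got = round(pk.gc_content(records[plasmid]), 1)
            check(f"{plasmid}_gc", abs(got - want) <= 0.1, f"{got} vs {want}")

    if "pMARC1" in records:
        got = round(pk.gc_content(records["pMARC1"], 1312, 3143), 1)
        check("pMARC1_islet_window_gc", abs(got - 35.7) <= 0.1,
              f"{got} vs 35.7")
        islets = pk.detect_islets(pk.gc_profile(records["pMARC1"]),
                                  records["pMARC1"])
        ok = any(abs(i.start - 1312) <= 200 and abs(i.end - 3143) <= 200
                 and abs(i.islet_gc - 35.7) <= 1.5 for i in islets)
        check("pMARC1_islet_detection", ok,
              f"{[(i.start, i.end, i.islet_gc) for i in islets]}")

    if "pHAE2" in records:
        rec = records["pHAE2"]
        arrays = pk.find_direct_repeats(rec, min_unit=15, max_spacer=10)
        ok = any(a.n_units == 5 and a.unit_length == 19
                 and all(s == 3 for s in a.spacers) for a in arrays)
        check("pHAE2_five_19bp_repeats", ok,
              f"{[(a.n_units, a.unit_length, a.spacers) for a in arrays]}")

    def rep_protein(plasmid: str) -> str | None:
        if plasmid not in records:
            return None
        rec = records[plasmid]
        orfs = primary_orfs(find_orfs(rec), len(rec))
        best = None
        for orf in orfs:
            pred = pk.predict_oriV(rec, orf)
            if pred and pred.iteron_array is not None:
                if best is None or orf.length_codons > best.length_codons:
                    best = orf
        return best.aa_sequence if best else None

    rep1, rep7 = rep_protein("pMARC1"), rep_protein("pMOS7")
    if rep1 and rep7:
        ident = pk.global_align(rep1, rep7, molecule="aa").identity_pct
        check("pMARC1_pMOS7_rep_identity", abs(round(ident) - 96) <= 1,
              f"{ident:.1f} vs 96")

    def ta_region(plasmid: str) -> str | None:
        if plasmid not in records:
            return None
        rec = records[plasmid]
        orfs = primary_orfs(find_orfs(rec), len(rec))
        pairs = pk.detect_ta_pairs(orfs, len(rec))
        overlaps = [p for p in pairs if p.gap < 0]
        if not overlaps:
            return None
        p = overlaps[0]
        return orf_nt(rec, p.orf_a) + orf_nt(rec, p.orf_b)

    ta3, ta7 = ta_region("pAES3"), ta_region("pAES7")
    if ta3 and ta7:
        ident = pk.global_align(ta3, ta7, molecule="nt").identity_pct
        check("pAES3_pAES7_ta_identity", abs(round(ident) - 94) <= 1,
              f"{ident:.1f} vs 94")

    if "pAES1" in records:
        rec = records["pAES1"]
        irs = pk.find_inverted_repeats(rec, min_arm=20, max_loop=60,
                                       max_mismatch=5)
        ok = any(ir.arm_length >= 26 and ir.mismatches == 5 for ir in irs)
        check("pAES1_28bp_ir_5_mismatches", ok,
              f"{[(ir.arm_length, ir.mismatches) for ir in irs[:5]]}")

    return results


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True, type=Path)
    args = ap.parse_args()
    if not args.data_dir.is_dir():
        print(f"no such directory: {args.data_dir}", file=sys.stderr)
        return 2
    results = run_checks(args.data_dir)
    if not results:
        print("no recognizable records found", file=sys.stderr)
        return 2
    width = max(len(r.name) for r in results)
    failures = 0
    for r in results:
        status = "ok  " if r.passed else "FAIL"
        failures += not r.passed
        print(f"{status}  {r.name:<{width}}  {r.detail}")
    print(f"{len(results) - failures}/{len(results)} checks passed")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
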