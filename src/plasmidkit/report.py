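"""GFF3 and TSV report writers."""

from __future__ import annotations

from pathlib import Path
from urllib.parse import quote

import pandas as pd

from plasmidkit import __version__
from plasmidkit.annotate import GeneticModule, OriTPrediction, OriVPrediction, TAPair
from plasmidkit.genome import Orf, PlasmidRecord
from plasmidkit.islets import GCIslet

_MODULE_COLOR = {"REP": "blue", "MOB": "green", "TA": "red", "PAR": "orange",
                 "RM": "purple", "ACCESSORY": "grey"}


def _esc(value: str) -> str:
    return quote(str(value), safe=" :^*$@!+_?-|")


def _gff_line(seqid, source, ftype, start, end, score, strand, attrs) -> str:
    attr_str = ";".join(f"{k}={_esc(v)}" for k, v in attrs.items())
    return "\t".join([seqid, source, ftype, str(start), str(end),
                      score, strand, ".", attr_str])


def orf_gff_interval(orf: Orf, n: int) -> tuple[int, int]:
    lo, hi = orf.span(n)
    return lo + 1, min(hi, n) if hi <= n else hi  # wrap reported past length


def write_gff3(record: PlasmidRecord, modules: list[GeneticModule],
               islets: list[GCIslet], orfs: list[Orf], path: str | Path) -> None:
    n = len(record)
    lines = ["##gff-version 3",
             f"#!plasmidkit {__version__}",
             f"##sequence-region {record.id} 1 {n}"]
    counter = 0
    for m in modules:
        color = _MODULE_COLOR.get(m.kind, "grey")
        for member in m.members:
            counter += 1
            if isinstance(member, Orf):
                lo, hi = member.span(n)
                lines.append(_gff_line(
                    record.id, "plasmidkit", "CDS", lo + 1, hi, ".",
                    member.strand,
                    {"ID": f"orf{counter}", "module": m.kind,
                     "color": color, "codons": member.length_codons}))
            elif isinstance(member, OriVPrediction):
                r_start, r_end = member.region
                if r_end < r_start:   # wraps the origin: GFF3 circular style
                    r_end += n
                lines.append(_gff_line(
                    record.id, "plasmidkit", "rep_origin",
                    r_start, r_end, str(member.score), "+",
                    {"ID": f"oriv{counter}", "module": m.kind,
                     "Note": "predicted oriV", "color": color}))
            elif isinstance(member, OriTPrediction):
                site = member.site_start0 + 1
                lines.append(_gff_line(
                    record.id, "plasmidkit", "oriT", site,
                    site + len(member.hit.matched_sequence) - 1,
                    str(member.hit.mismatches), "+",
                    {"ID": f"orit{counter}", "module": m.kind,
                     "family": member.family_pattern, "color": color}))
            elif isinstance(member, TAPair):
                for tag, orf in (("toxin_or_antitoxin_a", member.orf_a),
                                 ("toxin_or_antitoxin_b", member.orf_b)):
                    counter += 1
                    lo, hi = orf.span(n)
                    lines.append(_gff_line(
                        record.id, "plasmidkit", "CDS", lo + 1, hi, ".",
                        orf.strand,
                        {"ID": f"orf{counter}", "module": "TA", "role": tag,
                         "gap": member.gap, "color": color}))
    for k, islet in enumerate(islets, 1):
        lines.append(_gff_line(
            record.id, "plasmidkit", "genomic_island", islet.start,
            islet.end - 1, ".", "+",
            {"ID": f"islet{k}", "gc": islet.islet_gc,
             "remaining_gc": islet.background_gc, "color": "yellow"}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_tsv(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame([
        {"plasmid": r["plasmid"], "size_bp": r["size_bp"],
         "gc_pct": r["gc_pct"], "n_orfs": r["n_orfs"],
         "modules": r["modules"]}
        for r in rows
    ])
    df.to_csv(path, sep="\t", index=False)


def write_islet_tsv(rows: list[dict], path: str | Path) -> None:
    flat = []
    for r in rows:
        for islet in r["islets"]:
            flat.append({
                "plasmid": r["plasmid"],
                "pi_size_bp": islet["size_bp"],
                "position": f"{islet['interval'][0]}-{islet['interval'][1]}",
                "pi_gc": islet["islet_gc"],
                "remaining_gc": islet["remaining_gc"],
                "orf_aa": ",".join(str(x) for x in islet["orfs_aa"]) or "-",
            })
    pd.DataFrame(flat, columns=["plasmid", "pi_size_bp", "position", "pi_gc",
                                "remaining_gc", "orf_aa"]).to_csv(
        path, sep="\t", index=False)


def write_profile_tsv(profile, path: str | Path) -> None:
    pd.DataFrame(profile.values, columns=["window_start", "gc_pct"]).to_csv(
        path, sep="\t", index=False)
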