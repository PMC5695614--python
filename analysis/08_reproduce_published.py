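#!/usr/bin/env python
"""Recompute published genome statistics from the deposited records.

Requires network access once, to fetch the deposited plastid (KU255795)
and mitochondrial (KU255794) genomes into data/published/:

    okit fetch KU255795 KU255794 --email you@example.org --out-dir data/published

Then recomputes genome size, GC content, inverted-repeat and quadripartite
layout, non-coding total, and start/stop codon tallies, printing each next
to the published value.
"""

from pathlib import Path

from okit.genome_io import (
    codon_usage_summary,
    find_inverted_repeats,
    gc_content,
    noncoding_total,
    parse_genbank,
    quadripartite,
)

PUBLISHED = Path(__file__).resolve().parent.parent / "data" / "published"

EXPECTED = {
    "pt_length": 124450, "pt_gc": 29.8, "ir_len": 5423,
    "ssc": 39858, "lsc": 73747, "pt_atg": 137, "pt_taa": 107,
    "mt_length": 35660, "mt_gc": 36.44, "mt_noncoding": 1640, "mt_atg": 37,
}


def main() -> None:
    pt_path = PUBLISHED / "KU255795.gb"
    mt_path = PUBLISHED / "KU255794.gb"
    if not (pt_path.exists() and mt_path.exists()):
        raise SystemExit(
            "deposited records not found under data/published/ — fetch them "
            "first with `okit fetch KU255795 KU255794 --email ... --out-dir "
            "data/published` (network required)"
        )
    pt = parse_genbank(pt_path)[0]
    mt = parse_genbank(mt_path)[0]

    def report(name, computed, published):
        flag = "OK" if computed == published else "MISMATCH"
        print(f"{name:16s} computed {computed!s:>10} published {published!s:>10}  {flag}")

    report("pt length", len(pt), EXPECTED["pt_length"])
    report("pt GC %", round(gc_content(pt), 1), EXPECTED["pt_gc"])
    irs = find_inverted_repeats(pt, min_len=1000)
    report("IR length", irs[0][2] if irs else 0, EXPECTED["ir_len"])
    if irs:
        layout = quadripartite(pt, irs[0])
        report("SSC", layout.ssc_len, EXPECTED["ssc"])
        report("LSC", layout.lsc_len, EXPECTED["lsc"])
    s = codon_usage_summary(pt)
    report("pt ATG starts", s.start_counts.get("ATG", 0), EXPECTED["pt_atg"])
    report("pt TAA stops", s.stop_counts.get("TAA", 0), EXPECTED["pt_taa"])

    report("mt length", len(mt), EXPECTED["mt_length"])
    report("mt GC %", round(gc_content(mt), 2), EXPECTED["mt_gc"])
    report("mt non-coding", noncoding_total(mt)[0], EXPECTED["mt_noncoding"])
    sm = codon_usage_summary(mt)
    report("mt ATG starts", sm.start_counts.get("ATG", 0), EXPECTED["mt_atg"])


if __name__ == "__main__":
    main()
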