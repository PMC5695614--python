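#!/usr/bin/env python
"""Identity scan, divergent regions, spacer markers and in-silico PCR.

On the collinear (mitochondrion-like) dataset: windowed identity of every
query against the reference genome, merging of persistently low-identity
windows into divergent regions, nomination of intergenic spacers inside
them with the length rules (too short for primer design / too long for a
single read), polymorphic-site counting across the taxa for one kept
spacer, and an in-silico PCR check of a primer pair bracketing it.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from okit._seq import revcomp
from okit.divergence_scan import (
    PrimerPair,
    anchored_identity,
    count_polymorphic_sites,
    divergent_regions,
    in_silico_pcr,
    spacer_candidates,
)
from okit.genome_io import parse_genbank

RESULTS = Path(__file__).resolve().parent.parent / "results"


def _mafft(seqs: dict[str, str]) -> dict[str, str]:
    """Nucleotide multiple alignment via mafft (on PATH)."""
    import subprocess, tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
        path = fh.name
    out = subprocess.run(
        ["mafft", "--quiet", "--auto", path], capture_output=True, text=True,
        check=True,
    ).stdout
    aligned, name = {}, None
    for line in out.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            aligned[name] = ""
        elif name:
            aligned[name] += line.strip().upper()
    return aligned


def main() -> None:
    data = RESULTS / "data" / "collinear"
    genomes = [parse_genbank(p)[0] for p in sorted(data.glob("*.gb"))]
    ref, queries = genomes[0], genomes[1:]

    tracks = [anchored_identity(ref, q, window=500, step=100) for q in queries]
    pd.DataFrame(
        [
            {"query": t.query_id, "ref_start": ws, "ref_end": we,
             "identity": round(ident, 4)}
            for t in tracks for ws, we, ident in t.windows
        ]
    ).to_csv(RESULTS / "identity_tracks.tsv", sep="\t", index=False)

    regions = divergent_regions(tracks, threshold=0.7)
    with open(RESULTS / "divergent_regions.bed", "w") as fh:
        for start, end in regions:
            fh.write(f"{ref.id}\t{start}\t{end}\n")
    spacers = spacer_candidates(regions, ref, min_len=200, max_len=1400,
                                tracks=tracks)
    kept = [s for s in spacers if s.verdict == "kept"]
    print(f"{len(regions)} divergent regions below 70% identity")
    print(f"{len(spacers)} overlapping spacers, {len(kept)} kept "
          f"({sum(s.verdict == 'too_short' for s in spacers)} too short, "
          f"{sum(s.verdict == 'too_long' for s in spacers)} too long)")

    if kept:
        target = kept[0]
        start, end = target.region
        seqs = {}
        for g in genomes:
            # the dataset is collinear, so the same flanking genes bound the
            # homologous spacer in every genome
            a = next(f for f in g.features if f.name == target.flanking[0])
            b = next(f for f in g.features if f.name == target.flanking[1])
            seqs[g.taxon] = g.sequence[a.spans[-1][1] : b.spans[0][0]]
        rows = list(_mafft(seqs).values())
        count, _, gapped = count_polymorphic_sites(rows)
        print(
            f"spacer {target.flanking[0]}-{target.flanking[1]} "
            f"({target.length} bp on the reference): {count} polymorphic "
            f"sites across {len(rows)} taxa "
            f"({len(gapped)} gap columns excluded)"
        )
        # primer pair bracketing the spacer on the reference
        fwd = ref.sequence[start - 21 : start]
        rev = revcomp(ref.sequence[end : end + 21])
        amps = in_silico_pcr(ref, PrimerPair(forward=fwd, reverse=rev))
        if amps:
            print(
                f"in-silico PCR: {len(amps)} amplicon(s), product "
                f"{amps[0].length} bp on strand {amps[0].strand}"
            )
    print("wrote results/identity_tracks.tsv, divergent_regions.bed")


if __name__ == "__main__":
    main()
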