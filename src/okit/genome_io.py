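"""Parsing of annotated organelle genomes and descriptive genome statistics.

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted at the parsing boundary.  Genomes are
treated as circular molecules: features whose location spans the origin are
unwrapped into multiple spans, and sequence extraction re-wraps them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._seq import revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "orf")


class GenomeParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted as a genome."""


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a circular genome.

    ``spans`` is an ordered list of [start, end) intervals in genomic
    coordinates; multiple spans arise from origin-wrapping locations or
    intron-split genes.  Spans are listed in *biological* order, so the
    feature's sequence is the concatenation of its spans, reverse
    complemented as a whole when ``strand`` is '-'.
    """

    name: str
    kind: str  # one of FEATURE_KINDS
    strand: str  # '+' or '-'
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.spans:
            raise ValueError(f"feature {self.name} has no spans")
        for start, end in self.spans:
            if start < 0 or end <= start:
                raise ValueError(f"feature {self.name}: bad span ({start}, {end})")

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.spans)

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (of the first span)."""
        return self.spans[0][0]


@dataclass
class OrganelleGenome:
    """A circular annotated organelle genome."""

    id: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    translation_table: int = 11
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.spans:
                if end > n:
                    raise GenomeParseError(
                        f"genome {self.id}: feature {feat.name} span ({start}, {end}) "
                        f"outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Strand-aware nucleotide sequence of a feature."""
        joined = "".join(self.sequence[s:e] for s, e in feature.spans)
        return revcomp(joined) if feature.strand == "-" else joined

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]


@dataclass(frozen=True)
class QuadripartiteLayout:
    """IRa / IRb / LSC / SSC partition of a quadripartite plastid genome.

    Each region is a (start, end) arc on the circle (end may be < start for
    an origin-wrapping arc) plus its length in bp.
    """

    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ir_len: int
    lsc_len: int
    ssc_len: int


# ---------------------------------------------------------------------------
# GenBank parsing


def _classify(feat_type: str, name: str) -> str | None:
    if feat_type == "CDS":
        return "orf" if name.lower().startswith("orf") else "CDS"
    if feat_type in ("tRNA", "rRNA"):
        return feat_type
    return None


def _feature_name(feat) -> str:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return ""


def parse_genbank(path: str | Path) -> list[OrganelleGenome]:
    """Parse a GenBank flat file into :class:`OrganelleGenome` records.

    One genome per LOCUS.  Origin-spanning ``join`` locations become
    multi-span features; strand is read from ``complement()``.  CDS whose
    total span length is not divisible by 3 are kept but flagged in the
    record-level ``frame_warnings`` attribute (not fatal).
    """
    genomes: list[OrganelleGenome] = []
    for record in SeqIO.parse(str(path), "genbank"):
        seq = str(record.seq)
        if not seq or set(seq) == {"N"}:
            raise GenomeParseError(f"record {record.id}: missing ORIGIN sequence")
        feats: list[GeneFeature] = []
        warnings: list[str] = []
        for feat in record.features:
            name = _feature_name(feat)
            kind = _classify(feat.type, name)
            if kind is None:
                continue
            if not name:
                warnings.append(f"unnamed {feat.type} feature at {feat.location}")
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            spans = tuple(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            for s, e in spans:
                if e > len(seq):
                    raise GenomeParseError(
                        f"record {record.id}: feature {name} outside sequence"
                    )
            gf = GeneFeature(name=name, kind=kind, strand=strand, spans=spans)
            if kind in ("CDS", "orf") and gf.length % 3 != 0:
                warnings.append(f"CDS {name}: length {gf.length} not divisible by 3")
            feats.append(gf)
        organism = record.annotations.get("organism", record.description or record.id)
        table = 11
        genome = OrganelleGenome(
            id=record.id, taxon=organism, sequence=seq, features=feats,
            translation_table=table,
        )
        genome.frame_warnings = warnings  # type: ignore[attr-defined]
        genomes.append(genome)
    if not genomes:
        raise GenomeParseError(f"no GenBank records found in {path}")
    return genomes


# ---------------------------------------------------------------------------
# Descriptive statistics


def gc_content(genome: OrganelleGenome | str) -> float:
    """GC percentage, N excluded from the denominator."""
    seq = genome if isinstance(genome, str) else genome.sequence
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def _span_union_size(length: int, spans: Iterable[tuple[int, int]]) -> int:
    """Size of the union of [start, end) spans on a circle of given length."""
    events: list[tuple[int, int]] = []
    for start, end in spans:
        if end <= length:
            events.append((start, end))
        else:  # wrapped span given in doubled coordinates
            events.append((start, length))
            events.append((0, end - length))
    if not events:
        return 0
    events.sort()
    total = 0
    cur_start, cur_end = events[0]
    for start, end in events[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start
    return total


def noncoding_total(genome: OrganelleGenome) -> tuple[int, float]:
    """(bp, percent) of the genome not covered by any annotated feature."""
    covered = _span_union_size(
        len(genome), (s for f in genome.features for s in f.spans)
    )
    bp = len(genome) - covered
    return bp, 100.0 * bp / len(genome)


@dataclass
class CodonUsageSummary:
    start_counts: dict[str, int]
    stop_counts: dict[str, int]
    non_atg_genes: list[tuple[str, str]]  # (gene, start codon)
    excluded: list[str]  # CDS skipped (length not divisible by 3)

    @property
    def n_cds(self) -> int:
        return sum(self.start_counts.values())


def codon_usage_summary(
    genome: OrganelleGenome, kinds: Sequence[str] = ("CDS", "orf")
) -> CodonUsageSummary:
    """Tally strand-aware start and stop codons of every in-frame CDS."""
    starts: dict[str, int] = {}
    stops: dict[str, int] = {}
    non_atg: list[tuple[str, str]] = []
    excluded: list[str] = []
    for feat in genome.features_of_kind(*kinds):
        cds = genome.feature_sequence(feat)
        if len(cds) % 3 != 0 or len(cds) < 6:
            excluded.append(feat.name)
            continue
        first, last = cds[:3], cds[-3:]
        starts[first] = starts.get(first, 0) + 1
        stops[last] = stops.get(last, 0) + 1
        if first != "ATG":
            non_atg.append((feat.name, first))
    return CodonUsageSummary(starts, stops, non_atg, excluded)


# ---------------------------------------------------------------------------
# Inverted repeats and the quadripartite layout


def find_inverted_repeats(
    genome: OrganelleGenome | str,
    min_len: int = 1000,
    max_seed_hits: int = 200,
) -> list[tuple[int, int, int]]:
    """Find maximal inverted-repeat pairs on the circular sequence.

    Returns (posA, posB, length) triples — two disjoint segments where the
    segment at ``posB`` equals the reverse complement of the one at
    ``posA`` — longest first.  Exact matching (no mismatches); detection is
    seed-and-extend with ``min_len``-capped 20-mers, so repeats shorter than
    ``min_len`` are not reported.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    seq = genome if isinstance(genome, str) else genome.sequence
    n = len(seq)
    if n < 2 * min_len:
        return []
    k = min(min_len, 20)
    doubled = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(doubled[i : i + k], []).append(i)

    found: set[tuple[int, int, int]] = set()
    seen_pairs: set[tuple[int, int]] = set()
    for i in range(n):
        kmer = doubled[i : i + k]
        partners = index.get(revcomp(kmer))
        if not partners or len(partners) > max_seed_hits:
            continue
        for j in partners:
            if j == i:
                continue
            # extend the seed pair maximally on the circle
            a0, b0 = i, j  # seq[a0:a0+k] == revcomp(seq[b0:b0+k])
            length = k
            while length < n:
                na = (a0 - 1) % n
                nb_end = (b0 + length) % n
                if seq[na] == revcomp(seq[nb_end]) and na != nb_end:
                    a0, length = na, length + 1
                else:
                    break
            while length < n:
                nb = (b0 - 1) % n
                na_end = (a0 + length) % n
                if seq[nb] == revcomp(seq[na_end]) and nb != na_end:
                    b0, length = nb, length + 1
                else:
                    break
            if length < min_len:
                continue
            a, b = sorted((a0, b0))
            if (a, b) in seen_pairs:
                continue
            seen_pairs.add((a, b))
            # reject self-overlapping pairs (on the circle)
            if _arcs_overlap(a, length, b, length, n):
                continue
            found.add((a, b, length))
    return sorted(found, key=lambda t: (-t[2], t[0], t[1]))


def _arcs_overlap(a: int, la: int, b: int, lb: int, n: int) -> bool:
    pos_a = {(a + i) % n for i in range(la)}
    pos_b = {(b + i) % n for i in range(lb)}
    return bool(pos_a & pos_b)


def quadripartite(
    genome: OrganelleGenome, ir_pair: tuple[int, int, int]
) -> QuadripartiteLayout:
    """Label the two arcs between an IR pair as LSC (longer) and SSC (shorter)."""
    a, b, length = ir_pair
    n = len(genome)
    if _arcs_overlap(a, length, b, length, n):
        raise ValueError("IR copies overlap; quadripartite layout undefined")
    ira = (a, (a + length) % n)
    irb = (b, (b + length) % n)
    arc1 = (ira[1], b)  # from end of IRa to start of IRb
    arc2 = (irb[1], a)
    len1 = (b - ira[1]) % n
    len2 = (a - irb[1]) % n
    if len1 == 0 or len2 == 0:
        raise ValueError("IR copies are adjacent; a single-copy arc has length 0")
    if len1 >= len2:
        lsc, lsc_len, ssc, ssc_len = arc1, len1, arc2, len2
    else:
        lsc, lsc_len, ssc, ssc_len = arc2, len2, arc1, len1
    return QuadripartiteLayout(
        ira=ira, irb=irb, lsc=lsc, ssc=ssc,
        ir_len=length, lsc_len=lsc_len, ssc_len=ssc_len,
    )


# ---------------------------------------------------------------------------
# Reports


def stats_row(genome: OrganelleGenome, ir_min_len: int = 1000) -> dict:
    """One row of the per-genome statistics report (TSV-ready dict)."""
    nc_bp, nc_pct = noncoding_total(genome)
    kinds = {k: len(genome.features_of_kind(k)) for k in FEATURE_KINDS}
    irs = find_inverted_repeats(genome, min_len=ir_min_len) if ir_min_len else []
    row = {
        "id": genome.id,
        "taxon": genome.taxon,
        "length_bp": len(genome),
        "gc_percent": round(gc_content(genome), 2),
        "n_cds": kinds["CDS"],
        "n_cds_plus_orf": kinds["CDS"] + kinds["orf"],
        "n_trna": kinds["tRNA"],
        "n_rrna": kinds["rRNA"],
        "noncoding_bp": nc_bp,
        "noncoding_percent": round(nc_pct, 2),
        "ir_len": irs[0][2] if irs else 0,
        "lsc_len": "",
        "ssc_len": "",
    }
    if irs:
        try:
            layout = quadripartite(genome, irs[0])
            row["lsc_len"] = layout.lsc_len
            row["ssc_len"] = layout.ssc_len
        except ValueError:
            pass
    return row
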