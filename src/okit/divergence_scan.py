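"""Sliding-window identity scans of collinear genomes and marker nomination.

Mirrors the circular-map comparison workflow used for collinear
mitochondrial genomes: shared single-copy genes anchor a collinear map
between a reference and each query, inter-anchor segments are globally
aligned, and identity is computed in windows tiling the reference.
Windows persistently below an identity threshold across queries are merged
into divergent regions; intergenic spacers overlapping them are nominated
as population-genetic markers subject to practical length bounds, and a
primer pair can be tested by in-silico PCR on the circular molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import revcomp
from .genome_io import OrganelleGenome

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class IdentityTrack:
    """Windowed identity of one query against the reference."""

    ref_id: str
    query_id: str
    windows: list[tuple[int, int, float]]  # (ref_start, ref_end, identity)

    def values(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows])


class CollinearityError(ValueError):
    pass


def _single_copy_positions(
    genome: OrganelleGenome,
) -> dict[str, tuple[int, int, str]]:
    """gene -> (leftmost start, rightmost end, strand) for single-copy genes."""
    counts: dict[str, int] = {}
    for f in genome.features:
        counts[f.name] = counts.get(f.name, 0) + 1
    return {
        f.name: (
            min(s for s, _ in f.spans),
            max(e for _, e in f.spans),
            f.strand,
        )
        for f in genome.features
        if counts[f.name] == 1
    }


def _is_circular_rotation(a: list[str], b: list[str]) -> bool:
    if len(a) != len(b) or set(a) != set(b):
        return False
    doubled = b + b
    for i in range(len(b)):
        if doubled[i : i + len(a)] == a:
            return True
    return False


def anchored_identity(
    ref: OrganelleGenome,
    query: OrganelleGenome,
    window: int = 500,
    step: int = 100,
) -> IdentityTrack:
    """Identity of ``query`` against ``ref`` in windows tiling the reference.

    Shared single-copy genes anchor a collinear map (the query is reverse
    complemented if its anchor chain runs backwards); each inter-anchor
    segment is globally aligned and per-reference-position match/column
    counts are accumulated, insertions counting against the position to
    their left.  Identity per window = matches / alignment columns.
    """
    ref_anchors = _single_copy_positions(ref)
    qry_anchors = _single_copy_positions(query)
    shared = sorted(set(ref_anchors) & set(qry_anchors))
    if len(shared) < 3:
        raise CollinearityError(
            f"only {len(shared)} shared single-copy anchors; need >= 3"
        )
    ref_order = sorted(shared, key=lambda g: ref_anchors[g][0])
    qry_order = sorted(shared, key=lambda g: qry_anchors[g][0])
    qseq = query.sequence
    if not _is_circular_rotation(ref_order, qry_order):
        if _is_circular_rotation(ref_order, qry_order[::-1]):
            n = len(qseq)
            qry_anchors = {
                g: (n - end, n - start, "-" if strand == "+" else "+")
                for g, (start, end, strand) in qry_anchors.items()
            }
            qseq = revcomp(qseq)
            qry_order = sorted(shared, key=lambda g: qry_anchors[g][0])
        else:
            raise CollinearityError(
                "anchor chain is not collinear; genomes appear rearranged "
                "(use the rearrangement module instead)"
            )

    ref_len, qry_len = len(ref), len(qseq)
    matches = np.zeros(ref_len)
    columns = np.zeros(ref_len)
    n_anchors = len(ref_order)
    # rotate the query anchor list so it starts at ref_order[0]
    offset = qry_order.index(ref_order[0])
    qry_order = qry_order[offset:] + qry_order[:offset]
    for i in range(n_anchors):
        g0, g1 = ref_order[i], ref_order[(i + 1) % n_anchors]
        r0, r1 = ref_anchors[g0][0], ref_anchors[g1][0]
        q0, q1 = qry_anchors[g0][0], qry_anchors[g1][0]
        rseg = _arc(ref.sequence, r0, r1)
        qseg = _arc(qseq, q0, q1)
        if not rseg or not qseg:
            continue
        _accumulate(rseg, qseg, r0, ref_len, matches, columns)

    windows = []
    for start in range(0, ref_len, step):
        idx = np.arange(start, start + window) % ref_len
        cols = columns[idx].sum()
        ident = float(matches[idx].sum() / cols) if cols > 0 else 0.0
        windows.append((start, min(start + window, ref_len), ident))
    return IdentityTrack(ref_id=ref.id, query_id=query.id, windows=windows)


def _arc(seq: str, start: int, end: int) -> str:
    return seq[start:end] if end >= start else seq[start:] + seq[:end]


def _accumulate(
    rseg: str, qseg: str, r_offset: int, ref_len: int,
    matches: np.ndarray, columns: np.ndarray,
) -> None:
    result = edlib.align(qseg, rseg, mode="NW", task="path")
    r = 0  # position within rseg
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        count = int(count)
        if op == "=":
            for k in range(count):
                pos = (r_offset + r + k) % ref_len
                matches[pos] += 1
                columns[pos] += 1
            r += count
        elif op in ("X", "M"):
            for k in range(count):
                columns[(r_offset + r + k) % ref_len] += 1
            r += count
        elif op == "I":  # query-only columns: charge the position to the left
            columns[(r_offset + max(r - 1, 0)) % ref_len] += count
        elif op == "D":  # reference-only columns (gap in query)
            for k in range(count):
                columns[(r_offset + r + k) % ref_len] += 1
            r += count


# ---------------------------------------------------------------------------
# Divergent regions


def divergent_regions(
    tracks: list[IdentityTrack],
    threshold: float = 0.7,
    min_query_fraction: float = 0.5,
) -> list[tuple[int, int]]:
    """Merged reference regions whose windows fall below ``threshold``
    identity in at least ``min_query_fraction`` of the queries."""
    if not tracks:
        return []
    ref_ids = {t.ref_id for t in tracks}
    if len(ref_ids) != 1:
        raise ValueError(f"tracks have mixed references: {sorted(ref_ids)}")
    n_windows = len(tracks[0].windows)
    flagged = []
    for w in range(n_windows):
        below = sum(t.windows[w][2] < threshold for t in tracks)
        if below / len(tracks) >= min_query_fraction:
            flagged.append(tracks[0].windows[w][:2])
    return merge_intervals(flagged)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# Spacer candidates


@dataclass
class SpacerCandidate:
    region: tuple[int, int]
    flanking: tuple[str, str]
    length: int
    verdict: str  # kept | too_short | too_long
    mean_identity: float = float("nan")


def intergenic_spacers(
    genome: OrganelleGenome,
) -> list[tuple[int, int, str, str]]:
    """(start, end, left gene, right gene) spacers between annotated features
    on the circle (end < start marks an origin-wrapping spacer)."""
    feats = sorted(genome.features, key=lambda f: f.start)
    if not feats:
        return []
    spans = []
    for f in feats:
        start = min(s for s, _ in f.spans)
        end = max(e for _, e in f.spans)
        spans.append((start, end, f.name))
    spacers = []
    for i in range(len(spans)):
        _, end_i, name_i = spans[i]
        start_j, _, name_j = spans[(i + 1) % len(spans)]
        if i == len(spans) - 1:  # wrap
            gap = (start_j - end_i) % len(genome)
            if gap > 0:
                spacers.append((end_i, start_j, name_i, name_j))
        elif start_j > end_i:
            spacers.append((end_i, start_j, name_i, name_j))
    return spacers


def spacer_candidates(
    regions: list[tuple[int, int]],
    genome: OrganelleGenome,
    min_len: int = 200,
    max_len: int = 1400,
    tracks: list[IdentityTrack] | None = None,
) -> list[SpacerCandidate]:
    """Intersect divergent regions with intergenic spacers and apply the
    length rules (too short for primers, too long for one Sanger read)."""
    spacers = intergenic_spacers(genome)
    n = len(genome)
    out = []
    for start, end, left, right in spacers:
        length = (end - start) % n or (end - start)
        overlapping = any(
            _circ_overlap(start, end, r0, r1, n) for r0, r1 in regions
        )
        if not overlapping:
            continue
        if length < min_len:
            verdict = "too_short"
        elif length > max_len:
            verdict = "too_long"
        else:
            verdict = "kept"
        mean_ident = float("nan")
        if tracks:
            vals = [
                ident
                for t in tracks
                for ws, we, ident in t.windows
                if _circ_overlap(start, end, ws, we, n)
            ]
            if vals:
                mean_ident = float(np.mean(vals))
        out.append(
            SpacerCandidate(
                region=(start, end), flanking=(left, right),
                length=length, verdict=verdict, mean_identity=mean_ident,
            )
        )
    return out


def _circ_overlap(a0: int, a1: int, b0: int, b1: int, n: int) -> bool:
    def positions(s, e):
        if e >= s:
            return set(range(s, e))
        return set(range(s, n)) | set(range(0, e))

    return bool(positions(a0, a1) & positions(b0, b1))


# ---------------------------------------------------------------------------
# Polymorphic sites


def count_polymorphic_sites(
    rows: list[str],
) -> tuple[int, list[int], list[int]]:
    """(count, polymorphic positions, gap-containing positions).

    A column is polymorphic when it holds >= 2 distinct non-gap states;
    columns containing a gap are excluded from the count and reported
    separately.
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    poly, gapped = [], []
    for i in range(len(rows[0])):
        column = {r[i].upper() for r in rows}
        if "-" in column:
            gapped.append(i)
            continue
        if len(column - {"N"}) >= 2:
            poly.append(i)
    return len(poly), poly, gapped


# ---------------------------------------------------------------------------
# In-silico PCR


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        self.forward = self.forward.replace(" ", "").upper()
        self.reverse = self.reverse.replace(" ", "").upper()
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if set(seq) - set("ACGT"):
                raise ValueError(f"{label} primer has non-ACGT characters")
            if len(seq) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt")


@dataclass
class Amplicon:
    start: int  # 0-based position of the forward primer's 5' end
    end: int  # exclusive end (may exceed genome length: origin-wrapping)
    length: int
    strand: str  # '+': forward primer on the plus strand


def _primer_sites(
    seq2: str, primer: str, n: int, max_mismatch: int, three_prime_exact: int,
    three_prime_right: bool,
) -> list[int]:
    """Start positions (in [0, n)) where the primer binds the given text.

    ``three_prime_right`` marks whether the primer's 3' terminus maps to the
    right end of the occurrence (plus-strand binding) or to the left end
    (minus-strand binding of the reverse-complemented text).
    """
    m = len(primer)
    sites = []
    for i in range(n):
        window = seq2[i : i + m]
        mism = sum(a != b for a, b in zip(window, primer))
        if mism > max_mismatch:
            continue
        tail = (
            (window[-three_prime_exact:], primer[-three_prime_exact:])
            if three_prime_right
            else (window[:three_prime_exact], primer[:three_prime_exact])
        )
        if tail[0] != tail[1]:
            continue
        sites.append(i)
    return sites


def in_silico_pcr(
    genome: OrganelleGenome | str,
    primers: PrimerPair,
    max_mismatch: int = 0,
    max_product: int = 5000,
    three_prime_exact: int = 5,
) -> list[Amplicon]:
    """Predict amplicons of a primer pair on a circular template.

    The forward primer may bind either strand; the reverse primer must bind
    the opposite strand downstream within ``max_product``.  Products
    include both primer sites; origin-wrapping products are allowed.  Even
    when mismatches are tolerated the 3'-terminal ``three_prime_exact``
    nucleotides must match exactly.
    """
    seq = genome if isinstance(genome, str) else genome.sequence
    n = len(seq)
    seq2 = seq + seq
    f, r = primers.forward, primers.reverse
    amplicons: list[Amplicon] = []
    # plus-strand product: forward primer on +, reverse primer on -
    fwd_plus = _primer_sites(seq2, f, n, max_mismatch, three_prime_exact, True)
    rev_minus = _primer_sites(
        seq2, revcomp(r), n, max_mismatch, three_prime_exact, False
    )
    for s in fwd_plus:
        for t in rev_minus:
            t_adj = t if t >= s else t + n
            end = t_adj + len(r)
            length = end - s
            if len(f) + len(r) <= length <= max_product:
                amplicons.append(Amplicon(s, end, length, "+"))
    # minus-strand product: forward primer on -, reverse primer on +
    fwd_minus = _primer_sites(
        seq2, revcomp(f), n, max_mismatch, three_prime_exact, False
    )
    rev_plus = _primer_sites(seq2, r, n, max_mismatch, three_prime_exact, True)
    for s in rev_plus:
        for t in fwd_minus:
            t_adj = t if t >= s else t + n
            end = t_adj + len(f)
            length = end - s
            if len(f) + len(r) <= length <= max_product:
                amplicons.append(Amplicon(s, end, length, "-"))
    amplicons.sort(key=lambda a: (a.start, a.end, a.strand))
    return amplicons
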