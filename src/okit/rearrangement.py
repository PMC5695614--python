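"""Signed gene orders and the double-cut-and-join (DCJ) rearrangement distance.

A genome is reduced to the circular order of its single-copy markers with
orientation signs.  The DCJ distance between two genomes over the same
marker set is d = N - (C + I/2), where C and I are the numbers of cycles
and odd paths of the adjacency graph over marker extremities; for two
single circular chromosomes I = 0.  A breadth-first-search oracle over
genome states provides an exact, formula-independent check on small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

Marker = tuple[str, int]  # (gene id, sign in {+1, -1})


class MarkerSetError(ValueError):
    pass


@dataclass(frozen=True)
class SignedGeneOrder:
    """Circular ordered list of signed single-copy markers."""

    markers: tuple[Marker, ...]
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("gene order must be non-empty")
        genes = [g for g, _ in self.markers]
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise MarkerSetError(f"duplicated markers: {dup}")
        for _, sign in self.markers:
            if sign not in (1, -1):
                raise ValueError("signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.markers}

    def rotated(self, k: int) -> "SignedGeneOrder":
        k %= len(self.markers)
        return SignedGeneOrder(self.markers[k:] + self.markers[:k], self.genome_id)

    def flipped(self) -> "SignedGeneOrder":
        """The same circular molecule read from the other strand."""
        return SignedGeneOrder(
            tuple((g, -s) for g, s in reversed(self.markers)), self.genome_id
        )


def extract_signed_order(genome, markers: set[str] | None = None) -> SignedGeneOrder:
    """Signed order of single-copy genes in genomic position order.

    ``markers`` restricts the gene set; duplicated genes (e.g. IR copies)
    are excluded automatically when no explicit set is given, and are an
    error when explicitly requested.
    """
    feats = [f for f in genome.features if f.kind in ("CDS", "rRNA", "orf")]
    by_name: dict[str, list] = {}
    for f in feats:
        by_name.setdefault(f.name, []).append(f)
    if markers is None:
        wanted = {name for name, fs in by_name.items() if len(fs) == 1}
    else:
        wanted = set(markers)
        dup = sorted(m for m in wanted if len(by_name.get(m, [])) != 1)
        if dup:
            raise MarkerSetError(
                f"markers duplicated or missing in {genome.id}: {dup}"
            )
    chosen = [by_name[name][0] for name in wanted]
    chosen.sort(key=lambda f: f.start)
    return SignedGeneOrder(
        tuple((f.name, 1 if f.strand == "+" else -1) for f in chosen),
        genome_id=genome.id,
    )


# ---------------------------------------------------------------------------
# Adjacency graph and the distance formula

Extremity = tuple[str, str]  # (gene, 'h' | 't')


def adjacencies(order: SignedGeneOrder) -> set[frozenset]:
    """Adjacency set of a circular signed order over marker extremities.

    A marker traversed with sign + enters at its tail and leaves at its
    head (and vice versa for sign -); an adjacency joins the exit extremity
    of each marker to the entry extremity of its successor.
    """
    adj: set[frozenset] = set()
    ms = order.markers
    for i, (gene, sign) in enumerate(ms):
        nxt_gene, nxt_sign = ms[(i + 1) % len(ms)]
        exit_ext = (gene, "h" if sign == 1 else "t")
        entry_ext = (nxt_gene, "t" if nxt_sign == 1 else "h")
        adj.add(frozenset((exit_ext, entry_ext)))
    return adj


def _partner_map(adj: set[frozenset]) -> dict[Extremity, Extremity]:
    partners: dict[Extremity, Extremity] = {}
    for pair in adj:
        elems = tuple(pair)
        if len(elems) == 1:  # self-adjacency: a one-marker circle
            partners[elems[0]] = elems[0]
        else:
            a, b = elems
            partners[a] = b
            partners[b] = a
    return partners


def dcj_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """DCJ distance d = N - (C + I/2) from the adjacency graph."""
    if a.genes != b.genes:
        diff = sorted(a.genes ^ b.genes)
        raise MarkerSetError(f"marker sets differ: {diff}")
    n = len(a)
    pa = _partner_map(adjacencies(a))
    pb = _partner_map(adjacencies(b))
    extremities = [(g, e) for g in sorted(a.genes) for e in ("h", "t")]
    seen: set[Extremity] = set()
    cycles = 0
    odd_paths = 0
    for start in extremities:
        if start in seen:
            continue
        # walk the component alternating A- and B-adjacencies
        cur, use_a, edges = start, True, 0
        while True:
            seen.add(cur)
            partner = (pa if use_a else pb).get(cur)
            if partner is None:  # telomere: path end (not hit for circular input)
                break
            edges += 1
            cur = partner
            use_a = not use_a
            if cur == start and use_a:
                cycles += 1
                break
            if cur in seen and cur != start:
                break
        else:  # pragma: no cover
            pass
        if cur != start or not use_a:
            if edges % 2 == 1:
                odd_paths += 1
    return n - (cycles + odd_paths // 2)


# ---------------------------------------------------------------------------
# BFS oracle (exact search over genome states; small instances only)


def _order_to_matching(order: SignedGeneOrder, gene_index: dict[str, int]) -> tuple:
    """Encode the adjacency set as a partner tuple over extremities 0..2N-1
    (gene i: tail=2i, head=2i+1)."""
    m = [0] * (2 * len(gene_index))
    for pair in adjacencies(order):
        elems = tuple(pair)
        if len(elems) == 1:
            x = _ext_id(elems[0], gene_index)
            m[x] = x
        else:
            x, y = (_ext_id(e, gene_index) for e in elems)
            m[x], m[y] = y, x
    return tuple(m)


def _ext_id(ext: Extremity, gene_index: dict[str, int]) -> int:
    gene, he = ext
    return 2 * gene_index[gene] + (1 if he == "h" else 0)


def _neighbors(state: tuple) -> Iterable[tuple]:
    """All states one DCJ operation away (operations on two adjacencies)."""
    pairs = [(x, state[x]) for x in range(len(state)) if x <= state[x]]
    for i in range(len(pairs)):
        p, q = pairs[i]
        for j in range(i + 1, len(pairs)):
            r, s = pairs[j]
            for (w, x), (y, z) in (((p, r), (q, s)), ((p, s), (q, r))):
                nxt = list(state)
                nxt[w], nxt[x] = x, w
                nxt[y], nxt[z] = z, y
                yield tuple(nxt)


def dcj_bfs_oracle(a: SignedGeneOrder, b: SignedGeneOrder, max_ops: int = 16) -> int:
    """Exact minimal DCJ operation count by bidirectional breadth-first
    search over genome states.  Intended for <= 8 markers."""
    if a.genes != b.genes:
        raise MarkerSetError("marker sets differ")
    if len(a) > 8:
        raise ValueError("BFS oracle limited to <= 8 markers")
    gene_index = {g: i for i, g in enumerate(sorted(a.genes))}
    sa = _order_to_matching(a, gene_index)
    sb = _order_to_matching(b, gene_index)
    if sa == sb:
        return 0
    front: dict[tuple, int] = {sa: 0}
    back: dict[tuple, int] = {sb: 0}
    frontier_f, frontier_b = {sa}, {sb}
    for _ in range(max_ops):
        # expand the smaller frontier
        if len(frontier_f) <= len(frontier_b):
            frontier, dist_map, other = frontier_f, front, back
        else:
            frontier, dist_map, other = frontier_b, back, front
        new_frontier: set[tuple] = set()
        best = None
        for state in frontier:
            d = dist_map[state]
            for nxt in _neighbors(state):
                if nxt in other:
                    cand = d + 1 + other[nxt]
                    best = cand if best is None else min(best, cand)
                if nxt not in dist_map:
                    dist_map[nxt] = d + 1
                    new_frontier.add(nxt)
        if best is not None:
            return best
        if frontier is frontier_f:
            frontier_f = new_frontier
        else:
            frontier_b = new_frontier
        if not new_frontier:
            break
    raise RuntimeError(f"target not reached within {max_ops} operations")


# ---------------------------------------------------------------------------
# Collinear-run collapsing


def _oriented_pairs(order: SignedGeneOrder) -> dict[tuple, tuple[int, int]]:
    """Normalized oriented adjacency -> position pair.  The key identifies a
    consecutive pair up to reading direction."""
    out = {}
    ms = order.markers
    for i in range(len(ms)):
        x, y = ms[i], ms[(i + 1) % len(ms)]
        fwd = (x, y)
        rev = ((y[0], -y[1]), (x[0], -x[1]))
        key = min(fwd, rev)
        out[key] = (i, (i + 1) % len(ms))
    return out


def collapse_adjacencies(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    """Merge maximal runs identical (up to joint inversion) in both genomes
    into super-markers.  The DCJ distance is invariant under this reduction
    (each shared adjacency removes one marker and one trivial cycle)."""
    if a.genes != b.genes:
        raise MarkerSetError("marker sets differ")
    a_cur, b_cur = a, b
    while len(a_cur) > 1:
        shared = set(_oriented_pairs(a_cur)) & set(_oriented_pairs(b_cur))
        if not shared:
            break
        (x, y) = sorted(shared)[0]
        merged_name = f"{x[0]}|{y[0]}"
        a_cur = _merge_pair(a_cur, x, y, merged_name)
        b_cur = _merge_pair(b_cur, x, y, merged_name)
    return a_cur, b_cur


def _merge_pair(
    order: SignedGeneOrder, x: Marker, y: Marker, name: str
) -> SignedGeneOrder:
    ms = list(order.markers)
    n = len(ms)
    for i in range(n):
        cur, nxt = ms[i], ms[(i + 1) % n]
        if (cur, nxt) == (x, y):
            new = (name, 1)
            break
        if (cur, nxt) == ((y[0], -y[1]), (x[0], -x[1])):
            new = (name, -1)
            break
    else:  # pragma: no cover - callers guarantee the pair exists
        raise ValueError("pair not adjacent")
    j = (i + 1) % n
    if j > i:
        out = ms[:i] + [new] + ms[j + 1:]
    else:  # wrap: pair occupies last and first position
        out = [new] + ms[1:i]
    return SignedGeneOrder(tuple(out), order.genome_id)


# ---------------------------------------------------------------------------
# UniMoG-dialect serialization


def write_orders(orders: Sequence[SignedGeneOrder], path: str | Path) -> None:
    """One '>name' header plus one space-separated signed line per genome,
    ')' terminating each circular chromosome (UniMoG-compatible)."""
    lines = []
    for order in orders:
        lines.append(f">{order.genome_id}")
        body = " ".join(
            (g if s == 1 else f"-{g}") for g, s in order.markers
        )
        lines.append(f"{body} )")
    Path(path).write_text("\n".join(lines) + "\n")


def read_orders(path: str | Path) -> list[SignedGeneOrder]:
    orders = []
    name = ""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            continue
        tokens = [t for t in line.split() if t != ")"]
        markers = tuple(
            (t.lstrip("-"), -1 if t.startswith("-") else 1) for t in tokens
        )
        orders.append(SignedGeneOrder(markers, genome_id=name))
    return orders
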