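"""Gene-name harmonization, presence/absence matrices, and Dollo gain/loss
mapping on a fixed species tree.

Organelle genome annotations use inconsistent gene names across records
(e.g. the same photosystem gene deposited as ``psb28`` or ``psbW``), so
comparisons start from a curated synonym map.  Under Dollo parsimony each
gene is gained exactly once on the tree — at the most recent common
ancestor of the taxa carrying it — and any absence below that node is
explained by losses only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

# A small curated default synonym table in the spirit of a unified organelle
# annotation: canonical name -> aliases seen in deposited records.
DEFAULT_SYNONYMS: dict[str, set[str]] = {
    "psbW": {"psb28"},
    "ycf17": {"psb30", "ycf17-like"},
    "psbA": {"psba"},
    "rbcL": {"rbcl", "cbbL"},
    "rbcS": {"cbbS"},
    "tufA": {"tufa", "EF-Tu"},
    "secA": {"ftsI-like"},
    "atpA": {"atp1"},
    "atpB": {"atp2"},
    "nad11": {"nad11a"},
    "rnl": {"23S", "rrnL", "23S ribosomal RNA"},
    "rns": {"16S", "16S ribosomal RNA"},
    "rrn5": {"5S", "5S ribosomal RNA"},
}

_TRNA_RE = re.compile(
    r"^(?:trn|tRNA[-_ ]?)([A-Za-z]{1,3})[-_ ]?\(?([acgtu]{3})?\)?$", re.IGNORECASE
)

_AA_THREE_TO_ONE = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def normalize_trna_name(name: str) -> str | None:
    """Normalize tRNA names to ``trnX(anticodon)`` form; None if not a tRNA."""
    m = _TRNA_RE.match(name.strip())
    if not m:
        return None
    aa, anticodon = m.group(1), m.group(2)
    if len(aa) == 3 and aa.lower() in _AA_THREE_TO_ONE:
        aa = _AA_THREE_TO_ONE[aa.lower()]
    elif len(aa) != 1:
        return None
    anticodon = (anticodon or "nnn").lower().replace("u", "t")
    return f"trn{aa.upper()}({anticodon})"


class SynonymMapError(ValueError):
    pass


@dataclass
class SynonymMap:
    """canonical gene name -> set of aliases; application is idempotent."""

    table: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._alias_to_canonical: dict[str, str] = {}
        for canonical, aliases in self.table.items():
            for alias in aliases:
                key = alias.lower()
                prev = self._alias_to_canonical.get(key)
                if prev is not None and prev != canonical:
                    raise SynonymMapError(
                        f"alias {alias!r} mapped to both {prev!r} and {canonical!r}"
                    )
                self._alias_to_canonical[key] = canonical
        # canonical names map to themselves so application is idempotent
        for canonical in self.table:
            self._alias_to_canonical.setdefault(canonical.lower(), canonical)

    @classmethod
    def default(cls) -> "SynonymMap":
        return cls({k: set(v) for k, v in DEFAULT_SYNONYMS.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymMap":
        """Two-column TSV: canonical <tab> alias (one alias per line)."""
        table: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            canonical, alias = line.split("\t")[:2]
            table.setdefault(canonical, set()).add(alias)
        return cls(table)

    def resolve(self, name: str) -> str | None:
        """Canonical name for ``name``, or None when unknown to the map."""
        trna = normalize_trna_name(name)
        if trna is not None:
            name = trna
        return self._alias_to_canonical.get(name.lower())


def harmonize(
    raw_names: list[str], synonyms: SynonymMap | None = None
) -> tuple[list[str], list[str]]:
    """Replace aliases by canonical names (case-insensitive, tRNA-normalized).

    Returns (canonical names in input order, unresolved names).  Unresolved
    names pass through unchanged (tRNA names still normalized) and are
    reported so curation gaps are visible.
    """
    synonyms = synonyms or SynonymMap.default()
    out: list[str] = []
    unresolved: list[str] = []
    for name in raw_names:
        resolved = synonyms.resolve(name)
        if resolved is None:
            resolved = normalize_trna_name(name) or name
            unresolved.append(name)
        out.append(resolved)
    return out, unresolved


# ---------------------------------------------------------------------------
# Presence matrix


@dataclass
class PresenceMatrix:
    """taxa x harmonized gene names, boolean, with optional copy counts."""

    data: pd.DataFrame  # index=taxa, columns=genes, dtype=bool
    kinds: dict[str, str] = field(default_factory=dict)  # gene -> feature kind
    multiplicity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValueError("presence matrix labels must be unique")
        self.data = self.data.astype(bool)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def present_taxa(self, gene: str) -> set[str]:
        return set(self.data.index[self.data[gene]])

    def to_tsv(self, path: str | Path) -> None:
        self.data.astype(int).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(bool))


def build_presence_matrix(
    genomes, synonyms: SynonymMap | None = None
) -> tuple[PresenceMatrix, dict[str, list[str]]]:
    """Presence matrix over a list of :class:`OrganelleGenome` records.

    Gene names are harmonized first; IR-duplicated genes are recorded with
    multiplicity > 1.  Returns the matrix and per-taxon unresolved names.
    """
    synonyms = synonyms or SynonymMap.default()
    counts: dict[str, dict[str, int]] = {}
    kinds: dict[str, str] = {}
    unresolved_by_taxon: dict[str, list[str]] = {}
    for genome in genomes:
        names = [f.name for f in genome.features]
        canon, unresolved = harmonize(names, synonyms)
        unresolved_by_taxon[genome.taxon] = unresolved
        row = counts.setdefault(genome.taxon, {})
        for feat, name in zip(genome.features, canon):
            row[name] = row.get(name, 0) + 1
            kinds.setdefault(name, feat.kind)
    all_genes = sorted(kinds)
    taxa = list(counts)
    mult = pd.DataFrame(
        [[counts[t].get(g, 0) for g in all_genes] for t in taxa],
        index=taxa, columns=all_genes,
    )
    matrix = PresenceMatrix(data=mult > 0, kinds=kinds, multiplicity=mult)
    return matrix, unresolved_by_taxon


def core_genes(
    matrix: PresenceMatrix, kind_filter: set[str] | None = None
) -> set[str]:
    """Genes present in every taxon, optionally restricted to feature kinds."""
    if len(matrix.taxa) < 2:
        raise ValueError("core gene set needs at least 2 taxa")
    shared = set(matrix.data.columns[matrix.data.all(axis=0)])
    if kind_filter is not None:
        shared = {g for g in shared if matrix.kinds.get(g) in kind_filter}
    return shared


# ---------------------------------------------------------------------------
# Dollo gain/loss mapping


@dataclass
class EventMap:
    """Per-branch gained/lost genes.  Branches are keyed by the sorted,
    comma-joined leaf set of the child node (stable across tree drawings)."""

    gains: dict[str, list[str]] = field(default_factory=dict)
    losses: dict[str, list[str]] = field(default_factory=dict)

    def add_gain(self, branch: str, gene: str) -> None:
        self.gains.setdefault(branch, []).append(gene)

    def add_loss(self, branch: str, gene: str) -> None:
        self.losses.setdefault(branch, []).append(gene)

    def n_losses(self, gene: str) -> int:
        return sum(genes.count(gene) for genes in self.losses.values())

    def to_frame(self) -> pd.DataFrame:
        branches = sorted(set(self.gains) | set(self.losses))
        return pd.DataFrame(
            {
                "branch": branches,
                "gained": [",".join(sorted(self.gains.get(b, []))) for b in branches],
                "lost": [",".join(sorted(self.losses.get(b, []))) for b in branches],
            }
        )


def _branch_key(node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return ",".join(leaves)


def dollo_events(tree: dendropy.Tree, matrix: PresenceMatrix) -> EventMap:
    """Map each gene's single gain and minimal losses onto a rooted tree.

    The gain is placed on the branch above the most recent common ancestor
    of the presence leaves; one loss is placed on the branch above each
    maximal all-absent subtree below the gain node.  Leaves of the tree and
    taxa of the matrix must match exactly.
    """
    tree_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    matrix_taxa = set(matrix.taxa)
    if tree_taxa != matrix_taxa:
        diff = sorted(tree_taxa ^ matrix_taxa)
        raise ValueError(f"tree/matrix leaf mismatch: {diff}")

    events = EventMap()
    for gene in matrix.genes:
        present = matrix.present_taxa(gene)
        if not present:
            continue
        mrca = (
            tree.mrca(taxon_labels=sorted(present))
            if len(present) > 1
            else next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label in present
            )
        )
        events.add_gain(_branch_key(mrca), gene)
        _collect_losses(mrca, present, gene, events)
    return events


def _collect_losses(node, present: set[str], gene: str, events: EventMap) -> None:
    for child in node.child_nodes():
        leaves = {lf.taxon.label for lf in child.leaf_iter()}
        if leaves.isdisjoint(present):
            events.add_loss(_branch_key(child), gene)  # maximal absent subtree
        elif not leaves.issubset(present):
            _collect_losses(child, present, gene, events)


def ancestral_core(
    matrix: PresenceMatrix, tree: dendropy.Tree, outgroup: str
) -> set[str]:
    """Genes whose Dollo gain maps to the root of the ingroup, i.e. whose
    presence pattern (with the outgroup column included) places the gain at
    or above the ingroup ancestor — the putatively ancestral gene set."""
    events = dollo_events(tree, matrix)
    root_children = tree.seed_node.child_nodes()
    ingroup_nodes = [
        c for c in root_children
        if outgroup not in {lf.taxon.label for lf in c.leaf_iter()}
    ]
    ancestral: set[str] = set()
    root_key = _branch_key(tree.seed_node)
    ingroup_keys = {_branch_key(n) for n in ingroup_nodes}
    for branch, genes in events.gains.items():
        if branch == root_key or branch in ingroup_keys:
            ancestral.update(genes)
    return ancestral
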