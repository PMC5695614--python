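"""Distance-based tree building, bootstrap supports, and clade congruence.

Trees are inferred by neighbor joining on model-corrected distances with
nonparametric bootstrap supports (column resampling).  Externally computed
Newick trees can be supplied anywhere a tree is consumed, so a
likelihood-based pipeline can be dropped in unchanged.

Clade congruence follows the split-counting idea used to compare single-
gene trees against a concatenated reference: for every internal
bipartition of the reference topology, count how many gene trees contain
the same (unrooted, label-set based) bipartition with bootstrap support at
or above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .rates import CodonAlignment

Split = frozenset  # canonical side of an unrooted bipartition


# ---------------------------------------------------------------------------
# Supermatrix concatenation


def concat(
    alignments: list[CodonAlignment],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate gene alignments into a supermatrix plus partition table.

    Taxa missing from a gene are padded with gaps there.  Partitions are
    [start, end) column spans in gene order.
    """
    all_taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    shared = set(all_taxa)
    for aln in alignments:
        shared &= set(aln.taxa)
    if not shared:
        raise ValueError("no taxon common to all alignments")
    rows = {t: [] for t in all_taxa}
    partitions = []
    offset = 0
    for aln in alignments:
        length = aln.length_nt
        by_taxon = dict(zip(aln.taxa, aln.rows))
        for t in all_taxa:
            rows[t].append(by_taxon.get(t, "-" * length))
        partitions.append((aln.gene, offset, offset + length))
        offset += length
    return {t: "".join(parts) for t, parts in rows.items()}, partitions


# ---------------------------------------------------------------------------
# Distances


MAX_DISTANCE = 5.0


def distance_matrix(
    rows: dict[str, str], model: str = "jc-nt"
) -> tuple[list[str], np.ndarray]:
    """Pairwise corrected distances between aligned rows.

    Models: ``p-dist`` (raw proportion), ``jc-nt`` (Jukes-Cantor,
    d = -(3/4)ln(1-(4/3)p)), ``poisson-aa`` (d = -ln(1-p)).  Saturated
    pairs are capped at :data:`MAX_DISTANCE`.
    """
    labels = list(rows)
    n = len(labels)
    if n < 3:
        raise ValueError("distance matrix needs >= 3 taxa")
    seqs = [rows[t].upper() for t in labels]
    mat = np.zeros((n, n))
    skip = set("-N?X")
    for i in range(n):
        for j in range(i + 1, n):
            same = diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in skip or b in skip:
                    continue
                if a == b:
                    same += 1
                else:
                    diff += 1
            total = same + diff
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            p = diff / total
            mat[i, j] = mat[j, i] = _correct(p, model)
    return labels, mat


def _correct(p: float, model: str) -> float:
    if model == "p-dist":
        return p
    if model == "jc-nt":
        return -0.75 * np.log(1 - 4 * p / 3) if p < 0.75 else MAX_DISTANCE
    if model == "poisson-aa":
        return -np.log(1 - p) if p < 1.0 else MAX_DISTANCE
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(labels: list[str], matrix: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted); negative branch lengths clamped to 0.

    The agglomeration itself is scikit-bio's neighbor joining (array-index
    tie-breaking, so results are reproducible across processes); the result
    is returned as a dendropy tree for downstream handling.
    """
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.tree import nj as _skbio_nj

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)) or not np.allclose(
        matrix, matrix.T
    ):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) < 4:
        raise ValueError("neighbor joining needs >= 4 taxa")
    newick = str(_skbio_nj(_SkbioDM(matrix, labels)))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[Split]:
    """Nontrivial unrooted bipartitions as canonical leaf-label sets.

    The canonical side is the one containing the lexicographically smallest
    leaf label, which makes containment invariant to rotation and rooting.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full = frozenset(leaves)
    anchor = leaves[0]
    splits: set[Split] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        splits.add(side if anchor in side else full - side)
    return splits


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class SupportedTree:
    """An unrooted tree plus per-bipartition bootstrap supports (0-100)."""

    tree: dendropy.Tree
    supports: dict[Split, float] = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def splits(self) -> set[Split]:
        return tree_splits(self.tree)

    def to_newick(self) -> str:
        """Newick with supports written as internal-node labels."""
        tree = self.tree.clone(depth=1)
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        full, anchor = frozenset(leaves), leaves[0]
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            key = side if anchor in side else full - side
            if key in self.supports:
                node.label = f"{self.supports[key]:.0f}"
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def bootstrap_support(
    rows: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    model: str = "jc-nt",
) -> SupportedTree:
    """NJ tree on the full alignment with nonparametric bootstrap supports.

    Columns are resampled with replacement per replicate; support of an
    original internal bipartition is the percentage of replicate trees
    containing it.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, mat = distance_matrix(rows, model)
    tree = nj_tree(labels, mat)
    original = tree_splits(tree)
    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    taxa = list(rows)
    arr = np.array([list(rows[t]) for t in taxa])
    length = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_rows = {
            t: "".join(arr[i, cols]) for i, t in enumerate(taxa)
        }
        try:
            rep_labels, rep_mat = distance_matrix(rep_rows, model)
            rep_splits = tree_splits(nj_tree(rep_labels, rep_mat))
        except ValueError:
            continue
        for s in original & rep_splits:
            counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return SupportedTree(tree=tree, supports=supports)


# ---------------------------------------------------------------------------
# Clade congruence


@dataclass
class CladeCongruenceReport:
    """Per reference bipartition: k gene trees containing it (with support
    >= threshold) out of n gene trees."""

    rows: list[dict]  # {"split": Split, "k": int, "n": int}

    def fraction_full(self) -> float:
        """Fraction of reference bipartitions found in every gene tree."""
        if not self.rows:
            return float("nan")
        return sum(r["k"] == r["n"] for r in self.rows) / len(self.rows)


def clade_congruence(
    ref: SupportedTree | dendropy.Tree,
    gene_trees: list[SupportedTree],
    min_support: float = 50.0,
) -> CladeCongruenceReport:
    """Count, per internal reference bipartition, the gene trees containing
    it with support >= ``min_support``.

    Gene trees missing taxa are handled by restricting each reference
    bipartition to the gene's taxon set before containment testing.
    """
    ref_tree = ref.tree if isinstance(ref, SupportedTree) else ref
    ref_splits = tree_splits(ref_tree)
    ref_taxa = frozenset(lf.taxon.label for lf in ref_tree.leaf_node_iter())
    n = len(gene_trees)
    rows = []
    for split in sorted(ref_splits, key=sorted):
        k = 0
        for gt in gene_trees:
            gt_taxa = gt.taxa
            if not gt_taxa <= ref_taxa:
                raise ValueError(
                    f"gene tree has taxa outside the reference: "
                    f"{sorted(gt_taxa - ref_taxa)}"
                )
            restricted = _restrict_split(split, ref_taxa, gt_taxa)
            if restricted is None:
                continue
            gene_splits = gt.splits()
            if restricted in gene_splits and (
                gt.supports.get(restricted, 100.0) >= min_support
            ):
                k += 1
        rows.append({"split": split, "k": k, "n": n})
    return CladeCongruenceReport(rows=rows)


def _restrict_split(
    split: Split, ref_taxa: frozenset, gene_taxa: frozenset
) -> Split | None:
    side_a = frozenset(split) & gene_taxa
    side_b = (ref_taxa - split) & gene_taxa
    if len(side_a) < 2 or len(side_b) < 2:
        return None  # trivial after restriction
    anchor = min(gene_taxa)
    return side_a if anchor in side_a else side_b


def read_newick(path_or_string: str, is_path: bool = True) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are taken as supports."""
    if is_path:
        tree = dendropy.Tree.get(path=str(path_or_string), schema="newick")
    else:
        tree = dendropy.Tree.get(data=path_or_string, schema="newick")
    return tree


def supported_tree_from_newick(newick: str) -> SupportedTree:
    """Parse Newick whose internal labels are bootstrap supports."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full, anchor = frozenset(leaves), leaves[0]
    supports: dict[Split, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = side if anchor in side else full - side
        supports[key] = value
    tree.is_rooted = False
    return SupportedTree(tree=tree, supports=supports)
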