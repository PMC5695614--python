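#!/usr/bin/env python
"""Gene-order rearrangement analysis.

Encodes each simulated genome as a circular signed gene order over the
single-copy markers shared per pair and computes all pairwise DCJ
distances.  Distances are compared against the number of inversions the
simulator actually applied along the connecting tree path (the distance
can never exceed that count).
"""

import itertools
import json
from pathlib import Path

import dendropy

from okit.genome_io import parse_genbank
from okit.pipeline import pairwise_dcj
from okit.rearrangement import extract_signed_order, write_orders

RESULTS = Path(__file__).resolve().parent.parent / "results"


def _path_ops(tree, truth_ops, taxon_a, taxon_b):
    """Total applied inversions along the tree path between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    a = tree.taxon_namespace.get_taxon(taxon_a)
    b = tree.taxon_namespace.get_taxon(taxon_b)
    mrca = pdm.mrca(a, b)
    total = 0
    for leaf_taxon in (a, b):
        node = tree.find_node_with_taxon(lambda t: t is leaf_taxon)
        while node is not mrca:
            key = ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
            total += truth_ops.get(key, 0)
            node = node.parent_node
    return total


def main() -> None:
    data = RESULTS / "data" / "main"
    genomes = [parse_genbank(p)[0] for p in sorted(data.glob("*.gb"))]
    truth = json.loads((data / "truth.json").read_text())
    tree = dendropy.Tree.get(path=str(data / "true_tree.nwk"), schema="newick")
    tree.is_rooted = True

    dcj = pairwise_dcj(genomes)
    dcj.to_csv(RESULTS / "dcj_distances.tsv", sep="\t")
    write_orders(
        [extract_signed_order(g) for g in genomes], RESULTS / "gene_orders.txt"
    )

    print("pairwise DCJ distances (shared single-copy markers):")
    print(dcj.to_string())
    bounded = 0
    pairs = list(itertools.combinations([g.taxon for g in genomes], 2))
    for ta, tb in pairs:
        applied = _path_ops(tree, truth["dcj_ops"], ta, tb)
        if dcj.loc[ta, tb] <= applied:
            bounded += 1
    print(
        f"\ndistance <= applied inversion count on the tree path: "
        f"{bounded}/{len(pairs)} pairs"
    )
    print("wrote results/dcj_distances.tsv and results/gene_orders.txt")


if __name__ == "__main__":
    main()
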