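"""Simulation of organelle-genome datasets with known evolutionary truth.

A root circular genome (protein-coding genes, a few rRNAs, fast-evolving
intergenic spacers) is evolved down a rooted species tree under:

* codon substitution per gene — nucleotide proposals with transition bias
  kappa arrive as a Poisson process scaled by branch length; proposals
  creating a stop are rejected, synonymous proposals are accepted, and
  nonsynonymous ones are accepted with probability omega (a discrete
  M0-like scheme, so omega is the planted dN/dS);
* Dollo-style gene losses (a lost gene never returns) and lineage-specific
  orf gains on terminal branches;
* per-branch double-cut-and-join rearrangements realised as inversions of
  gene-bounded segments;
* spacer evolution at a rate multiplier over genes, with geometric-length
  indels so identity scans face realistic gaps (genes evolve without
  indels, keeping their codon alignments trivially true).

Everything is driven by one seeded generator, so identical seed + config
give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from ._seq import revcomp
from .genome_io import GeneFeature, OrganelleGenome
from .rates import _codons

# Mirrors the taxon structure of a small class-level organelle study: three
# nested ordinal clades plus a divergent outgroup lineage, eight taxa.
DEFAULT_TREE = (
    "((((FucA:0.02,FucB:0.02):0.02,FucC:0.04):0.03,"
    "((LamA:0.02,LamB:0.03):0.04,(EctA:0.04,EctB:0.04):0.03):0.02):0.03,"
    "Dict:0.12);"
)

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
BASES = "ACGT"


@dataclass
class GenePlan:
    name: str
    length_codons: int
    omega: float
    erratic: bool = False  # branch-heterogeneous rate -> high dN spread


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the scale of a class-level comparative organelle study:
    eight taxa, 170 protein-coding genes whose lengths straddle the 900 nt
    marker-length rule, mostly low omega with a minority of erratic
    high-omega genes, occasional gene loss, rare terminal orf gains, one
    rearrangement per branch, and spacers evolving several times faster
    than genes.
    """

    tree_newick: str = DEFAULT_TREE
    n_genes: int = 170
    gene_length_codons: tuple[int, int] = (60, 600)
    omega_slow: float = 0.05
    omega_fast: float = 0.5
    erratic_fraction: float = 0.16
    # Erratic genes are heterotachous: on every branch their rate is either
    # strongly depressed or strongly elevated (coin flip), which guarantees
    # that the planted 'erratic' label corresponds to a high spread of
    # pairwise dN values across taxon pairs.
    erratic_multipliers: tuple[float, float] = (0.1, 8.0)
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35)
    loss_rate: float = 0.02  # per gene per branch
    gain_prob: float = 0.25  # per terminal branch
    dcj_ops_per_branch: int = 1
    n_rrna: int = 3
    rrna_length: tuple[int, int] = (900, 1800)
    rrna_rate_multiplier: float = 0.3
    spacer_length: tuple[int, int] = (100, 500)
    spacer_rate_multiplier: float = 4.0
    spacer_indel_fraction: float = 0.1  # indel events per substitution event
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "omega_slow", "omega_fast", "erratic_fraction", "kappa",
            "loss_rate", "gain_prob", "spacer_rate_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genomes."""

    tree_newick: str
    losses: dict[str, list[str]] = field(default_factory=dict)  # branch -> genes
    gains: dict[str, list[str]] = field(default_factory=dict)
    dcj_ops: dict[str, int] = field(default_factory=dict)
    gene_omega: dict[str, float] = field(default_factory=dict)
    gene_erratic: dict[str, bool] = field(default_factory=dict)
    gene_length_nt: dict[str, int] = field(default_factory=dict)
    spacer_rate_multiplier: float = 1.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _branch_key(node) -> str:
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


# ---------------------------------------------------------------------------
# Sequence-level machinery


def _random_codon(rng: np.random.Generator, freqs, table_id: int = 1) -> str:
    codons = _codons(table_id)
    while True:
        codon = "".join(rng.choice(list(BASES), p=freqs) for _ in range(3))
        if codons[codon] != "*":
            return codon


def _random_gene(rng, n_codons: int, freqs) -> str:
    body = "".join(_random_codon(rng, freqs) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def _random_noncoding(rng, length: int, freqs) -> str:
    return "".join(rng.choice(list(BASES), p=freqs, size=length))


def _propose_base(rng, base: str, kappa: float) -> str:
    """Mutate one base with transition/transversion bias kappa."""
    others = [b for b in BASES if b != base]
    weights = np.array(
        [kappa if TRANSITIONS[base] == b else 1.0 for b in others]
    )
    return rng.choice(others, p=weights / weights.sum())


def evolve_cds(
    seq: str,
    branch_length: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
    table_id: int = 1,
    counts: dict[str, int] | None = None,
) -> str:
    """Evolve one in-frame CDS along a branch; first and last codons are
    protected so the reading frame, start and stop stay annotatable.

    ``counts`` (optional) accumulates the accepted 'syn'/'nonsyn'
    substitution events, giving the realised ground truth an estimator can
    be validated against.
    """
    if branch_length <= 0:
        return seq
    codons = _codons(table_id)
    chars = list(seq)
    mutable = len(seq) - 6
    if mutable <= 0:
        return seq
    n_events = rng.poisson(mutable * branch_length)
    for _ in range(n_events):
        pos = 3 + int(rng.integers(0, mutable))
        old = chars[pos]
        new = _propose_base(rng, old, kappa)
        c0 = 3 * (pos // 3)
        old_codon = "".join(chars[c0 : c0 + 3])
        new_codon = old_codon[: pos - c0] + new + old_codon[pos - c0 + 1 :]
        if codons[new_codon] == "*":
            continue
        synonymous = codons[new_codon] == codons[old_codon]
        if not synonymous and rng.random() >= omega:
            continue
        chars[pos] = new
        if counts is not None:
            key = "syn" if synonymous else "nonsyn"
            counts[key] = counts.get(key, 0) + 1
    return "".join(chars)


def evolve_noncoding(
    seq: str,
    branch_length: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
    indel_fraction: float = 0.0,
    min_length: int = 20,
) -> str:
    """Evolve a non-coding sequence: all substitutions accepted, optional
    geometric-length indels."""
    if branch_length <= 0 or not seq:
        return seq
    chars = list(seq)
    n_sub = rng.poisson(len(chars) * branch_length)
    for _ in range(n_sub):
        pos = int(rng.integers(0, len(chars)))
        chars[pos] = _propose_base(rng, chars[pos], kappa)
    if indel_fraction > 0:
        n_indel = rng.poisson(len(chars) * branch_length * indel_fraction)
        for _ in range(n_indel):
            length = int(rng.geometric(0.4))
            if rng.random() < 0.5 and len(chars) - length >= min_length:
                pos = int(rng.integers(0, len(chars) - length + 1))
                del chars[pos : pos + length]
            else:
                pos = int(rng.integers(0, len(chars) + 1))
                insert = [str(b) for b in rng.choice(list(BASES), size=length)]
                chars[pos:pos] = insert
    return "".join(chars)


def simulate_codon_gene(
    tree: dendropy.Tree | str,
    omega: float,
    kappa: float,
    length_codons: int,
    seed: int,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """Evolve one gene down a tree; returns per-taxon CDS strings."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(base_freqs)
    root_seq = _random_gene(rng, length_codons, freqs)
    out: dict[str, str] = {}
    _recurse_gene(tree.seed_node, root_seq, omega, kappa, rng, out)
    return out


def _recurse_gene(node, seq, omega, kappa, rng, out) -> None:
    if node.is_leaf():
        out[node.taxon.label] = seq
        return
    for child in node.child_nodes():
        t = child.edge.length or 0.0
        _recurse_gene(
            child, evolve_cds(seq, t, omega, kappa, rng), omega, kappa, rng, out
        )


# ---------------------------------------------------------------------------
# Whole-dataset simulation

Element = tuple[str, int, str]  # (id, sign, kind)


def _invert_random_segment(
    elements: list[Element], rng: np.random.Generator
) -> list[Element]:
    """Invert a random gene-bounded circular segment (a DCJ inversion).

    Segment endpoints are chosen at gene granularity so every operation
    rearranges the signed gene order; interior spacers travel with their
    genes.  The segment covers 1..n_genes-1 genes, never the whole circle.
    """
    gene_pos = [
        i for i, (_, _, kind) in enumerate(elements) if kind != "spacer"
    ]
    n = len(gene_pos)
    if n < 2:
        return elements
    length = int(rng.integers(1, n))
    start = int(rng.integers(0, n))
    rot = gene_pos[start]
    rotated = elements[rot:] + elements[:rot]  # harmless circular rotation
    gene_pos = [i for i, (_, _, kind) in enumerate(rotated) if kind != "spacer"]
    end_el = gene_pos[length - 1]
    segment = [(eid, -s, kind) for (eid, s, kind) in reversed(rotated[: end_el + 1])]
    return segment + rotated[end_el + 1 :]


def apply_random_inversions(order, n_ops: int, rng: np.random.Generator):
    """Apply ``n_ops`` random segment inversions to a bare signed gene order
    (the simulator's per-branch rearrangement step without sequences).
    Returns a new :class:`~okit.rearrangement.SignedGeneOrder`."""
    from .rearrangement import SignedGeneOrder

    elements: list[Element] = [(g, s, "CDS") for g, s in order.markers]
    for _ in range(n_ops):
        elements = _invert_random_segment(elements, rng)
    return SignedGeneOrder(
        tuple((g, s) for g, s, _ in elements), order.genome_id
    )


@dataclass
class _NodeState:
    elements: list[Element]
    seqs: dict[str, str]
    omega: dict[str, float]


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[OrganelleGenome], SimTruth]:
    """Simulate one dataset of circular annotated genomes plus its truth."""
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    tree.is_rooted = True
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.base_freqs)

    genes: list[GenePlan] = []
    n_erratic = int(round(config.erratic_fraction * config.n_genes))
    for i in range(config.n_genes):
        erratic = i < n_erratic
        length = int(rng.integers(*config.gene_length_codons))
        omega = config.omega_fast if erratic else float(
            rng.uniform(config.omega_slow, config.omega_slow * 4)
        )
        genes.append(GenePlan(f"g{i + 1:03d}", length, omega, erratic))

    truth = SimTruth(
        tree_newick=config.tree_newick,
        spacer_rate_multiplier=config.spacer_rate_multiplier,
    )
    seqs: dict[str, str] = {}
    omegas: dict[str, float] = {}
    elements: list[Element] = []
    rrna_names = ["rnl", "rns", "rrn5"][: config.n_rrna]
    all_units: list[tuple[str, str]] = [(g.name, "CDS") for g in genes] + [
        (r, "rRNA") for r in rrna_names
    ]
    order = rng.permutation(len(all_units))
    for gene in genes:
        seqs[gene.name] = _random_gene(rng, gene.length_codons, freqs)
        omegas[gene.name] = gene.omega
        truth.gene_omega[gene.name] = gene.omega
        truth.gene_erratic[gene.name] = gene.erratic
        truth.gene_length_nt[gene.name] = 3 * gene.length_codons
    for name in rrna_names:
        seqs[name] = _random_noncoding(
            rng, int(rng.integers(*config.rrna_length)), freqs
        )
    for k, idx in enumerate(order):
        name, kind = all_units[idx]
        sign = 1 if rng.random() < 0.5 else -1
        elements.append((name, sign, kind))
        spacer_id = f"s{k + 1:03d}"
        seqs[spacer_id] = _random_noncoding(
            rng, int(rng.integers(*config.spacer_length)), freqs
        )
        elements.append((spacer_id, 1, "spacer"))

    erratic_genes = {g.name for g in genes if g.erratic}
    root_state = _NodeState(elements=elements, seqs=seqs, omega=omegas)
    genomes: list[OrganelleGenome] = []
    lost_ever: set[str] = set()
    _recurse_dataset(
        tree.seed_node, root_state, config, rng, truth, genomes, erratic_genes,
        lost_ever, is_root=True,
    )
    genomes.sort(key=lambda g: g.taxon)
    return genomes, truth


def _recurse_dataset(
    node, state: _NodeState, config: SimConfig, rng, truth: SimTruth,
    genomes: list[OrganelleGenome], erratic_genes: set[str],
    lost_ever: set[str], is_root: bool = False,
) -> None:
    if node.is_leaf():
        genomes.append(_emit_genome(node.taxon.label, state))
        return
    for child in node.child_nodes():
        t = child.edge.length or 0.0
        key = _branch_key(child)
        child_seqs: dict[str, str] = {}
        child_elements = list(state.elements)

        # Losses are Dollo-style and kept identifiable: once lost, a gene is
        # never lost again on a parallel lineage, and no loss is placed on a
        # branch incident to the root (where a single-gain reconstruction
        # could absorb the event into "never gained").
        if is_root:
            lost: list[str] = []
        else:
            present_genes = [
                eid for eid, _, kind in child_elements if kind in ("CDS", "orf")
            ]
            lost = [
                g
                for g in present_genes
                if g not in lost_ever and rng.random() < config.loss_rate
            ]
            lost_ever.update(lost)
        if lost:
            truth.losses.setdefault(key, []).extend(lost)
            child_elements = [
                e for e in child_elements if e[0] not in lost
            ]

        # terminal-branch orf gains
        if child.is_leaf() and rng.random() < config.gain_prob:
            n_codons = int(rng.integers(60, 150))
            orf_name = f"orf{n_codons}_{child.taxon.label}"
            seq = _random_gene(rng, n_codons, np.asarray(config.base_freqs))
            pos = int(rng.integers(0, len(child_elements)))
            child_elements.insert(pos, (orf_name, 1, "orf"))
            state.seqs[orf_name] = seq
            state.omega[orf_name] = 0.2
            truth.gains.setdefault(key, []).append(orf_name)
            truth.gene_omega[orf_name] = 0.2
            truth.gene_erratic[orf_name] = False
            truth.gene_length_nt[orf_name] = 3 * n_codons

        # rearrangements
        n_ops = config.dcj_ops_per_branch
        for _ in range(n_ops):
            child_elements = _invert_random_segment(child_elements, rng)
        truth.dcj_ops[key] = n_ops

        # sequence evolution
        for eid, _, kind in child_elements:
            seq = state.seqs[eid]
            if kind in ("CDS", "orf"):
                mult = 1.0
                if eid in erratic_genes:
                    mult = float(rng.choice(config.erratic_multipliers))
                child_seqs[eid] = evolve_cds(
                    seq, t * mult, state.omega[eid], config.kappa, rng
                )
            elif kind == "rRNA":
                child_seqs[eid] = evolve_noncoding(
                    seq, t * config.rrna_rate_multiplier, rng, config.kappa
                )
            else:
                child_seqs[eid] = evolve_noncoding(
                    seq, t * config.spacer_rate_multiplier, rng, config.kappa,
                    indel_fraction=config.spacer_indel_fraction,
                )
        child_state = _NodeState(
            elements=child_elements,
            seqs={**state.seqs, **child_seqs},
            omega=state.omega,
        )
        _recurse_dataset(
            child, child_state, config, rng, truth, genomes, erratic_genes,
            lost_ever,
        )


def _emit_genome(taxon: str, state: _NodeState) -> OrganelleGenome:
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for eid, sign, kind in state.elements:
        seq = state.seqs[eid]
        if sign == -1:
            seq = revcomp(seq)
        if kind != "spacer":
            features.append(
                GeneFeature(
                    name=eid, kind=kind, strand="+" if sign == 1 else "-",
                    spans=((pos, pos + len(seq)),),
                )
            )
        parts.append(seq)
        pos += len(seq)
    return OrganelleGenome(
        id=f"SIM_{taxon}", taxon=taxon, sequence="".join(parts),
        features=features, translation_table=1,
    )


# ---------------------------------------------------------------------------
# GenBank emission


def genome_to_genbank(genome: OrganelleGenome) -> str:
    """Minimal legal GenBank flat-file text for one genome (LOCUS / FEATURES
    / ORIGIN), so the real parser is exercised on simulated data."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    import io

    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description=f"{genome.taxon} simulated organelle genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": genome.taxon,
            "date": "01-JAN-2020",
            "data_file_division": "PLN",
        },
    )
    for feat in genome.features:
        strand = 1 if feat.strand == "+" else -1
        locs = [FeatureLocation(s, e, strand=strand) for s, e in feat.spans]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = "CDS" if feat.kind == "orf" else feat.kind
        record.features.append(
            SeqFeature(location, type=ftype, qualifiers={"gene": [feat.name]})
        )
    buf = io.StringIO()
    SeqIO.write([record], buf, "genbank")
    return buf.getvalue()


def write_dataset(
    genomes: list[OrganelleGenome], truth: SimTruth, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        (outdir / f"{genome.taxon}.gb").write_text(genome_to_genbank(genome))
    (outdir / "true_tree.nwk").write_text(truth.tree_newick + "\n")
    truth.to_json(outdir / "truth.json")
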