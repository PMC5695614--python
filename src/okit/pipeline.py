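"""End-to-end pipeline: stats -> gene content -> DCJ -> rates -> trees ->
congruence -> divergence scan, with per-stage TSV/JSON reports.

Every stage output is a pure function of (inputs, config, seed); the only
non-deterministic artifact is the timing log, which is kept out of the
report files so reruns with one seed are byte-identical.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import divergence_scan, gene_content, genome_io, phylo, rates, rearrangement


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int
    genome_paths: list[Path] = field(default_factory=list)
    tree_path: Path | None = None
    min_len_nt: int = 900
    min_support: float = 50.0
    identity_thresholds: tuple[float, float] = (0.7, 0.5)
    spacer_bounds: tuple[int, int] = (200, 1400)
    bootstrap_reps: int = 100
    window: int = 500
    step: int = 100
    iqr_mode: str = "top-bin"
    ir_min_len: int = 1000

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.min_support <= 100:
            raise ValueError("min_support must be in (0, 100]")
        for t in self.identity_thresholds:
            if not 0 < t <= 1:
                raise ValueError("identity thresholds must be in (0, 1]")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _translate(cds: str, table_id: int) -> str:
    protein = str(Seq(cds).translate(table=table_id))
    return protein[:-1] if protein.endswith("*") else protein


def build_gene_alignments(
    genomes: list[genome_io.OrganelleGenome],
    gene_set: set[str],
    synonyms: gene_content.SynonymMap | None = None,
) -> list[rates.CodonAlignment]:
    """Protein-guided codon alignments for genes shared by all genomes."""
    synonyms = synonyms or gene_content.SynonymMap.default()
    alignments = []
    for gene in sorted(gene_set):
        cds: dict[str, str] = {}
        ok = True
        for genome in genomes:
            feats = [
                f
                for f in genome.features
                if f.kind in ("CDS", "orf")
                and (synonyms.resolve(f.name) or f.name) == gene
            ]
            if len(feats) != 1:
                ok = False
                break
            seq = genome.feature_sequence(feats[0])
            if len(seq) % 3 != 0:
                ok = False
                break
            cds[genome.taxon] = seq
        if not ok:
            continue
        table_id = genomes[0].translation_table
        stripped = {
            t: (s[:-3] if rates.is_stop(s[-3:], table_id) else s)
            for t, s in cds.items()
        }
        proteins = {t: _translate(s + "TAA", table_id) for t, s in stripped.items()}
        try:
            aligned = rates.align_proteins(proteins)
            alignments.append(
                rates.backtranslate(aligned, stripped, gene=gene, table_id=table_id)
            )
        except ValueError:
            continue
    return alignments


def pairwise_dcj(
    genomes: list[genome_io.OrganelleGenome],
) -> pd.DataFrame:
    """Symmetric DCJ distance matrix over shared single-copy markers."""
    taxa = [g.taxon for g in genomes]
    mat = pd.DataFrame(0, index=taxa, columns=taxa, dtype=int)
    orders = {g.taxon: rearrangement.extract_signed_order(g) for g in genomes}
    for a, b in itertools.combinations(genomes, 2):
        shared = orders[a.taxon].genes & orders[b.taxon].genes
        oa = rearrangement.extract_signed_order(a, markers=shared)
        ob = rearrangement.extract_signed_order(b, markers=shared)
        d = rearrangement.dcj_distance(oa, ob)
        mat.loc[a.taxon, b.taxon] = mat.loc[b.taxon, a.taxon] = d
    return mat


def run_pipeline(
    config: PipelineConfig,
    genomes: list[genome_io.OrganelleGenome] | None = None,
    tree: dendropy.Tree | None = None,
) -> dict:
    """Run every stage and write reports under ``config.out_dir``.

    Returns the summary dict (also written as summary.json).  Any stage
    failure raises :class:`PipelineError` naming the stage; earlier outputs
    are retained.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"seed": config.seed}

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                log_lines.append(f"{name}\tFAILED\t{exc}")
                (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(name, exc) from exc
            log_lines.append(f"{name}\tok\t{time.perf_counter() - t0:.2f}s")
            return result

        return wrap

    if genomes is None:
        if not config.genome_paths:
            raise PipelineError("input", ValueError("no genomes given"))
        genomes = _stage("parse")(
            lambda: [
                g
                for path in config.genome_paths
                for g in genome_io.parse_genbank(path)
            ]
        )
    if tree is None and config.tree_path is not None:
        tree = dendropy.Tree.get(path=str(config.tree_path), schema="newick")
        tree.is_rooted = True

    # -- stats ---------------------------------------------------------
    def stats_stage():
        df = pd.DataFrame(
            [genome_io.stats_row(g, ir_min_len=config.ir_min_len) for g in genomes]
        )
        df.to_csv(out / "genome_stats.tsv", sep="\t", index=False)
        codon = {
            g.taxon: {
                "starts": genome_io.codon_usage_summary(g).start_counts,
                "stops": genome_io.codon_usage_summary(g).stop_counts,
            }
            for g in genomes
        }
        (out / "codon_usage.json").write_text(
            json.dumps(codon, indent=1, sort_keys=True)
        )
        return df

    stats = _stage("stats")(stats_stage)
    summary["n_genomes"] = len(genomes)
    summary["mean_gc_percent"] = round(float(stats["gc_percent"].mean()), 3)

    # -- gene content --------------------------------------------------
    def content_stage():
        matrix, unresolved = gene_content.build_presence_matrix(genomes)
        matrix.to_tsv(out / "presence_matrix.tsv")
        core = gene_content.core_genes(matrix, kind_filter={"CDS"})
        events = None
        if tree is not None:
            events = gene_content.dollo_events(tree, matrix)
            events.to_frame().to_csv(out / "gene_events.tsv", sep="\t", index=False)
        return matrix, core, events

    matrix, core, events = _stage("content")(content_stage)
    summary["n_core_cds"] = len(core)

    # -- rearrangement -------------------------------------------------
    dcj = _stage("dcj")(lambda: pairwise_dcj(genomes))
    dcj.to_csv(out / "dcj_distances.tsv", sep="\t")
    vals = dcj.values[np.triu_indices(len(dcj), k=1)]
    summary["mean_dcj_distance"] = round(float(vals.mean()), 3) if len(vals) else 0.0

    # -- rates ---------------------------------------------------------
    def rates_stage():
        alignments = build_gene_alignments(genomes, core)
        summaries = [
            rates.gene_rate_summary(a, min_len_nt=config.min_len_nt)
            for a in alignments
        ]
        rates.assign_bins(summaries)
        candidates = rates.filter_candidates(
            summaries, iqr_mode=config.iqr_mode, min_len_nt=config.min_len_nt
        )
        rows = []
        cand_by_gene = {c.gene: c for c in candidates}
        for s in summaries:
            c = cand_by_gene.get(s.gene)
            rows.append(
                {
                    "gene": s.gene,
                    "length_nt": s.length_nt,
                    "n_pairs": s.n_pairs,
                    "median_dn": round(s.median_dn, 6),
                    "iqr": round(s.iqr, 6),
                    "dn_bin": s.dn_bin,
                    "iqr_bin": s.iqr_bin,
                    "candidate": bool(c and c.candidate),
                }
            )
        pd.DataFrame(rows).to_csv(out / "gene_rates.tsv", sep="\t", index=False)
        try:
            r, p = rates.rate_iqr_correlation(summaries)
        except ValueError:
            r, p = float("nan"), float("nan")
        return alignments, summaries, candidates, (r, p)

    alignments, summaries, candidates, (r, p) = _stage("rates")(rates_stage)
    summary["n_genes_scored"] = len(summaries)
    summary["n_candidates"] = sum(c.candidate for c in candidates)
    summary["dn_iqr_pearson_r"] = round(r, 4)

    # -- phylogeny + congruence ----------------------------------------
    def phylo_stage():
        cand_genes = {c.gene for c in candidates if c.candidate}
        cand_alns = [a for a in alignments if a.gene in cand_genes]
        if len(cand_alns) < 1 or len(genomes) < 4:
            return None, [], None
        rows, partitions = phylo.concat(cand_alns)
        ref = phylo.bootstrap_support(
            rows, n_reps=config.bootstrap_reps, seed=config.seed
        )
        (out / "concat_tree.nwk").write_text(ref.to_newick() + "\n")
        gene_trees = []
        for i, aln in enumerate(cand_alns):
            gt = phylo.bootstrap_support(
                dict(zip(aln.taxa, aln.rows)),
                n_reps=config.bootstrap_reps,
                seed=config.seed + i + 1,
            )
            gene_trees.append(gt)
        report = phylo.clade_congruence(
            ref, gene_trees, min_support=config.min_support
        )
        pd.DataFrame(
            [
                {
                    "bipartition": "|".join(sorted(r["split"])),
                    "k": r["k"],
                    "n": r["n"],
                }
                for r in report.rows
            ]
        ).to_csv(out / "congruence.tsv", sep="\t", index=False)
        return ref, gene_trees, report

    ref, gene_trees, congruence = _stage("phylo")(phylo_stage)
    if congruence is not None:
        summary["congruence_fraction_full"] = round(
            congruence.fraction_full(), 4
        )

    # -- divergence scan -----------------------------------------------
    def scan_stage():
        reference = genomes[0]
        tracks = []
        for query in genomes[1:]:
            try:
                tracks.append(
                    divergence_scan.anchored_identity(
                        reference, query, window=config.window, step=config.step
                    )
                )
            except divergence_scan.CollinearityError:
                continue
        if not tracks:
            return [], [], []
        rows = [
            {
                "query": t.query_id,
                "ref_start": ws,
                "ref_end": we,
                "identity": round(ident, 4),
            }
            for t in tracks
            for ws, we, ident in t.windows
        ]
        pd.DataFrame(rows).to_csv(out / "identity_tracks.tsv", sep="\t", index=False)
        regions = divergence_scan.divergent_regions(
            tracks, threshold=config.identity_thresholds[0]
        )
        with open(out / "divergent_regions.bed", "w") as fh:
            for start, end in regions:
                fh.write(f"{reference.id}\t{start}\t{end}\n")
        spacers = divergence_scan.spacer_candidates(
            regions, reference,
            min_len=config.spacer_bounds[0], max_len=config.spacer_bounds[1],
            tracks=tracks,
        )
        with open(out / "spacer_candidates.tsv", "w") as fh:
            fh.write("start\tend\tleft\tright\tlength\tverdict\n")
            for s in spacers:
                fh.write(
                    f"{s.region[0]}\t{s.region[1]}\t{s.flanking[0]}\t"
                    f"{s.flanking[1]}\t{s.length}\t{s.verdict}\n"
                )
        return tracks, regions, spacers

    tracks, regions, spacers = _stage("scan")(scan_stage)
    summary["n_divergent_regions"] = len(regions)
    summary["n_spacer_candidates_kept"] = sum(
        s.verdict == "kept" for s in spacers
    )

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary


REPORT_FILES = (
    "genome_stats.tsv", "codon_usage.json", "presence_matrix.tsv",
    "gene_events.tsv", "dcj_distances.tsv", "gene_rates.tsv",
    "concat_tree.nwk", "congruence.tsv", "identity_tracks.tsv",
    "divergent_regions.bed", "spacer_candidates.tsv", "summary.json",
)


def report_checksums(out_dir: Path) -> dict[str, str]:
    """sha256 of every deterministic report file present in ``out_dir``."""
    import hashlib

    out = {}
    for name in REPORT_FILES:
        path = Path(out_dir) / name
        if path.exists():
            out[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out
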