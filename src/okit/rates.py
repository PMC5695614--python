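"""Codon alignments, NG86 pairwise dN estimation, and marker-utility ranking.

The estimator is Nei-Gojobori (1986) counting with the Jukes-Cantor
correction: fractional synonymous/nonsynonymous site counts per codon from
the 9 single-nucleotide mutants, difference counts averaged equally over
all minimal mutational paths between two codons, and
dN = -(3/4)ln(1 - (4/3) pN).  Mutational steps through stop codons are
excluded from both the site and the difference tallies.

A gene's utility as a phylogenetic marker is scored by the median of its
pairwise dN values (divergence) and their interquartile range (uniformity
across the taxon pairs); candidate markers are genes outside the erratic
high-IQR class whose alignment is long enough for practical primer design.
"""

from __future__ import annotations

import itertools
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

BASES = "ACGT"
GAP_CODON = "---"


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def _codons(table_id: int) -> dict[str, str]:
    return _codon_map(table_id)


def is_stop(codon: str, table_id: int = 1) -> bool:
    return _codons(table_id).get(codon) == "*"


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class CodonAlignment:
    """Aligned codon rows (triplet columns, gap codon '---') for one gene."""

    gene: str
    taxa: list[str]
    rows: list[str]
    table_id: int = 1

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: ragged alignment rows")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{self.gene}: alignment length {length} not codon-sized")
        codons = _codons(self.table_id)
        for taxon, row in zip(self.taxa, self.rows):
            for i in range(0, length, 3):
                codon = row[i : i + 3]
                if codon != GAP_CODON and codons.get(codon) == "*" and i < length - 3:
                    raise ValueError(
                        f"{self.gene}/{taxon}: internal stop codon at column {i}"
                    )

    @property
    def length_nt(self) -> int:
        return len(self.rows[0])

    def codon_columns(self, i: int, j: int) -> list[tuple[str, str]]:
        """Codon pairs of rows i and j, excluding gapped/ambiguous columns
        and terminal stops."""
        ri, rj = self.rows[i], self.rows[j]
        out = []
        for k in range(0, len(ri), 3):
            ci, cj = ri[k : k + 3], rj[k : k + 3]
            if "-" in ci or "-" in cj or set(ci + cj) - set(BASES):
                continue
            if is_stop(ci, self.table_id) or is_stop(cj, self.table_id):
                continue
            out.append((ci, cj))
        return out


def backtranslate(
    protein_alignment: dict[str, str],
    cds_sequences: dict[str, str],
    gene: str = "",
    table_id: int = 1,
) -> CodonAlignment:
    """Thread CDS codons back through a protein alignment (TranslatorX-style).

    Each amino-acid column expands to its source codon; gaps become '---'.
    A terminal stop codon on the CDS is stripped before threading.
    """
    taxa = list(protein_alignment)
    rows = []
    for taxon in taxa:
        aa_row = protein_alignment[taxon]
        cds = cds_sequences[taxon].upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{gene}/{taxon}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and is_stop(codons[-1], table_id):
            codons = codons[:-1]
        ungapped = len(aa_row) - aa_row.count("-")
        if ungapped != len(codons):
            raise ValueError(
                f"{gene}/{taxon}: protein row has {ungapped} residues but CDS "
                f"provides {len(codons)} codons"
            )
        it = iter(codons)
        row = "".join(GAP_CODON if aa == "-" else next(it) for aa in aa_row)
        rows.append(row)
    return CodonAlignment(gene=gene, taxa=taxa, rows=rows, table_id=table_id)


def align_proteins(sequences: dict[str, str]) -> dict[str, str]:
    """Protein multiple alignment.  Equal-length inputs are returned as-is
    (already aligned); otherwise mafft is invoked."""
    if len({len(s) for s in sequences.values()}) == 1:
        return dict(sequences)
    if shutil.which("mafft") is None:  # pragma: no cover
        raise RuntimeError("mafft not found on PATH and inputs are unaligned")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.faa"
        inp.write_text(
            "".join(f">{t}\n{s}\n" for t, s in sequences.items())
        )
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", str(inp)],
            capture_output=True, text=True, check=True,
        )
    aligned: dict[str, str] = {}
    taxon = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            taxon = line[1:].strip()
            aligned[taxon] = ""
        elif taxon is not None:
            aligned[taxon] += line.strip()
    return aligned


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    syn = (1/3) * number of the 9 single-nucleotide mutants that code for
    the same amino acid; mutants that create a stop codon are excluded from
    the synonymous tally; nonsyn = 3 - syn.
    """
    codons = _codons(table_id)
    aa = codons.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"site counts undefined for codon {codon!r}")
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if codons[mutant] == aa:  # stop mutants never match a sense aa
                syn += 1
    syn_sites = syn / 3.0
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _pair_differences(
    ci: str, cj: str, table_id: int = 1
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged equally over all minimal mutational paths.  Paths that
    pass through a stop codon are discarded; if every path does, the codon
    pair contributes nothing (returned as zeros)."""
    if ci == cj:
        return 0.0, 0.0
    codons = _codons(table_id)
    positions = [k for k in range(3) if ci[k] != cj[k]]
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = ci
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
            if codons[nxt] == "*":
                ok = False
                break
            if codons[nxt] == codons[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0
    return syn_total / n_paths, nonsyn_total / n_paths


class SaturationError(ValueError):
    """pN too large for the Jukes-Cantor correction."""


def ng86_dn(
    row_i: str, row_j: str, table_id: int = 1, return_ds: bool = False
):
    """Pairwise NG86 dN (and optionally dS) between two aligned codon rows.

    Gapped or ambiguous codon columns are excluded pairwise.  Returns NaN
    components via :class:`SaturationError` when pN (pS) >= 3/4.
    """
    if len(row_i) != len(row_j) or len(row_i) % 3 != 0:
        raise ValueError("rows must be equal length and codon-sized")
    syn_sites_i = syn_sites_j = 0.0
    nd = sd = 0.0
    n_codons = 0
    for k in range(0, len(row_i), 3):
        ci, cj = row_i[k : k + 3], row_j[k : k + 3]
        if "-" in ci or "-" in cj or set(ci + cj) - set(BASES):
            continue
        if is_stop(ci, table_id) or is_stop(cj, table_id):
            continue
        si, _ = ng86_site_counts(ci, table_id)
        sj, _ = ng86_site_counts(cj, table_id)
        syn_sites_i += si
        syn_sites_j += sj
        s_diff, n_diff = _pair_differences(ci, cj, table_id)
        sd += s_diff
        nd += n_diff
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codon columns")
    s_sites = (syn_sites_i + syn_sites_j) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    pn = nd / n_sites
    if pn >= 0.75:
        raise SaturationError(f"pN = {pn:.3f} >= 3/4; dN saturated")
    dn = -0.75 * math.log(1.0 - 4.0 * pn / 3.0)
    if not return_ds:
        return dn
    ps = sd / s_sites if s_sites > 0 else float("nan")
    if ps >= 0.75:
        ds = float("nan")
    else:
        ds = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    return dn, ds


# ---------------------------------------------------------------------------
# Per-gene summaries and candidate filtering


@dataclass
class GeneRateSummary:
    gene: str
    length_nt: int
    pairwise_dn: dict[tuple[str, str], float]  # NaN for saturated pairs
    median_dn: float
    iqr: float
    dn_bin: int = -1
    iqr_bin: int = -1
    length_ok: bool = True
    usable: bool = True

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise_dn)


def gene_rate_summary(
    aln: CodonAlignment, min_len_nt: int = 900
) -> GeneRateSummary:
    """Median and IQR (type-7 linear-interpolation quantiles) over all
    defined pairwise dN values of one gene's alignment."""
    n = len(aln.taxa)
    if n < 3:
        raise ValueError("gene rate summary needs >= 3 taxa")
    pairwise: dict[tuple[str, str], float] = {}
    n_saturated = 0
    for i, j in itertools.combinations(range(n), 2):
        key = (aln.taxa[i], aln.taxa[j])
        try:
            pairwise[key] = ng86_dn(aln.rows[i], aln.rows[j], aln.table_id)
        except SaturationError:
            pairwise[key] = float("nan")
            n_saturated += 1
    values = np.array([v for v in pairwise.values() if not math.isnan(v)])
    usable = n_saturated <= len(pairwise) / 2 and len(values) > 0
    if len(values) == 0:
        median = iqr = float("nan")
    else:
        median = float(np.median(values))
        q1, q3 = np.percentile(values, [25, 75])  # type-7 interpolation
        iqr = float(q3 - q1)
    return GeneRateSummary(
        gene=aln.gene,
        length_nt=aln.length_nt,
        pairwise_dn=pairwise,
        median_dn=median,
        iqr=iqr,
        length_ok=aln.length_nt >= min_len_nt,
        usable=usable,
    )


def assign_bins(
    summaries: list[GeneRateSummary], n_bins: int = 3
) -> list[GeneRateSummary]:
    """Assign quantile bins (0 = lowest) for median dN and IQR in place."""
    usable = [s for s in summaries if s.usable]
    if not usable:
        return summaries
    med = np.array([s.median_dn for s in usable])
    iqr = np.array([s.iqr for s in usable])
    edges = np.linspace(0, 100, n_bins + 1)[1:-1]
    med_edges = np.percentile(med, edges)
    iqr_edges = np.percentile(iqr, edges)
    for s in usable:
        s.dn_bin = int(np.searchsorted(med_edges, s.median_dn, side="right"))
        s.iqr_bin = int(np.searchsorted(iqr_edges, s.iqr, side="right"))
    return summaries


def rate_iqr_correlation(
    summaries: list[GeneRateSummary],
) -> tuple[float, float]:
    """Pearson product-moment correlation between per-gene median dN and IQR."""
    usable = [s for s in summaries if s.usable]
    if len(usable) < 3:
        raise ValueError("correlation needs >= 3 usable genes")
    med = np.array([s.median_dn for s in usable])
    iqr = np.array([s.iqr for s in usable])
    if np.allclose(med, med[0]) or np.allclose(iqr, iqr[0]):
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(med, iqr)
    return float(r), float(p)


@dataclass
class MarkerCandidate:
    gene: str
    genome: str  # 'pt' | 'mt' | ''
    iqr_excluded: bool
    length_excluded: bool
    candidate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.candidate = not (self.iqr_excluded or self.length_excluded)


def filter_candidates(
    summaries: list[GeneRateSummary],
    iqr_mode: str = "top-bin",
    top_k: int | None = None,
    min_len_nt: int = 900,
    genome_label: str = "",
    n_bins: int = 3,
) -> list[MarkerCandidate]:
    """Apply the high-IQR exclusion and then the minimum-length rule.

    ``iqr_mode='top-bin'`` drops the highest IQR quantile bin;
    ``iqr_mode='top-k'`` drops exactly the ``top_k`` highest-IQR genes.
    The two rules are independent set memberships, so applying them in
    either order yields the same final candidate set.
    """
    usable = [s for s in summaries if s.usable]
    if iqr_mode == "top-k":
        if top_k is None:
            raise ValueError("top_k required for iqr_mode='top-k'")
        ranked = sorted(usable, key=lambda s: -s.iqr)
        excluded_iqr = {s.gene for s in ranked[:top_k]}
    elif iqr_mode == "top-bin":
        assign_bins(summaries, n_bins=n_bins)
        excluded_iqr = {s.gene for s in usable if s.iqr_bin == n_bins - 1}
    else:
        raise ValueError(f"unknown iqr_mode {iqr_mode!r}")
    out = []
    for s in usable:
        out.append(
            MarkerCandidate(
                gene=s.gene,
                genome=genome_label,
                iqr_excluded=s.gene in excluded_iqr,
                length_excluded=s.length_nt < min_len_nt,
            )
        )
    return out
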