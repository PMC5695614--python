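"""NG86 site/difference counting, codon alignments, marker filtering."""

import itertools
import math
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from okit.rates import (
    CodonAlignment,
    GeneRateSummary,
    SaturationError,
    assign_bins,
    backtranslate,
    filter_candidates,
    gene_rate_summary,
    ng86_dn,
    ng86_site_counts,
    rate_iqr_correlation,
)

BASES = "ACGT"
SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if str(Seq("".join(c)).translate(table=1)) != "*"
]


def _oracle_site_counts(codon):
    """Independent enumeration using Biopython translation."""
    aa = str(Seq(codon).translate(table=1))
    syn = 0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        mutant_aa = str(
            Seq(codon[:pos] + base + codon[pos + 1 :]).translate(table=1)
        )
        if mutant_aa == aa:
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _oracle_pair_diffs(ci, cj):
    """Independent minimal-path enumeration with Biopython translation."""
    if ci == cj:
        return 0.0, 0.0
    diff_pos = [k for k in range(3) if ci[k] != cj[k]]
    totals = []
    for perm in itertools.permutations(diff_pos):
        cur, syn, nonsyn, valid = ci, 0, 0, True
        for pos in perm:
            nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
            aa_cur = str(Seq(cur).translate(table=1))
            aa_nxt = str(Seq(nxt).translate(table=1))
            if aa_nxt == "*":
                valid = False
                break
            if aa_nxt == aa_cur:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if valid:
            totals.append((syn, nonsyn))
    if not totals:
        return 0.0, 0.0
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def _oracle_dn(row_i, row_j):
    n_sites = 0.0
    nd = 0.0
    n_codons = 0
    for k in range(0, len(row_i), 3):
        ci, cj = row_i[k : k + 3], row_j[k : k + 3]
        si = _oracle_site_counts(ci)
        sj = _oracle_site_counts(cj)
        n_sites += ((3 - si[0]) + (3 - sj[0])) / 2
        nd += _oracle_pair_diffs(ci, cj)[1]
        n_codons += 1
    pn = nd / n_sites
    return -0.75 * math.log(1 - 4 * pn / 3)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,syn,nonsyn",
        [("TTT", 1 / 3, 8 / 3), ("ATG", 0.0, 3.0), ("GGG", 1.0, 2.0)],
    )
    def test_known_codons(self, codon, syn, nonsyn):
        got = ng86_site_counts(codon)
        assert got[0] == pytest.approx(syn)
        assert got[1] == pytest.approx(nonsyn)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            assert ng86_site_counts(codon) == pytest.approx(
                _oracle_site_counts(codon)
            )

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")


class TestPairwiseDn:
    def test_identical_rows_zero(self):
        row = "ATGAAACCCGGG"
        assert ng86_dn(row, row) == pytest.approx(0.0)

    def test_symmetry(self):
        a, b = "ATGAAACCC", "ATGAGACCA"
        assert ng86_dn(a, b) == pytest.approx(ng86_dn(b, a))

    def test_matches_path_enumeration_oracle(self):
        """50 random codon-row pairs agree with an independent NG86
        implementation to 1e-12."""
        rnd = random.Random(17)
        for _ in range(50):
            n = rnd.randrange(5, 30)
            row_i = "".join(rnd.choice(SENSE_CODONS) for _ in range(n))
            row_j = "".join(
                c if rnd.random() < 0.7 else rnd.choice(SENSE_CODONS)
                for c in (row_i[k : k + 3] for k in range(0, len(row_i), 3))
            )
            try:
                got = ng86_dn(row_i, row_j)
            except SaturationError:
                continue
            assert got == pytest.approx(_oracle_dn(row_i, row_j), abs=1e-12)

    def test_gap_columns_excluded_pairwise(self):
        a = "ATG---AAA"
        b = "ATGCCCAAA"
        assert ng86_dn(a, b) == pytest.approx(0.0)

    def test_saturation_reported(self):
        a = "ATG" + "AAA" * 30
        b = "ATG" + "CCC" * 30
        with pytest.raises(SaturationError):
            ng86_dn(a, b)


class TestBacktranslate:
    def test_ungapped_rows_equal_cds_triplets(self):
        aln = backtranslate(
            {"x": "MK", "y": "MR"}, {"x": "ATGAAA", "y": "ATGAGA"}, gene="toy"
        )
        assert aln.rows == ["ATGAAA", "ATGAGA"]

    def test_gap_threading(self):
        aln = backtranslate(
            {"x": "M-K", "y": "MAK"}, {"x": "ATGAAA", "y": "ATGGCAAAG"}
        )
        assert aln.rows == ["ATG---AAA", "ATGGCAAAG"]

    def test_terminal_stop_stripped(self):
        aln = backtranslate({"x": "MK", "y": "MK"},
                            {"x": "ATGAAATAA", "y": "ATGAAG"})
        assert aln.rows[0] == "ATGAAA"

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="codons"):
            backtranslate({"x": "MKK"}, {"x": "ATGAAA"})

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(gene="g", taxa=["x"], rows=["ATGTAAAAA"])


class TestGeneRateSummary:
    def test_identical_alignment_zero_median_and_iqr(self):
        aln = CodonAlignment(
            gene="g", taxa=["a", "b", "c"], rows=["ATGAAACCC"] * 3
        )
        s = gene_rate_summary(aln)
        assert s.median_dn == 0.0 and s.iqr == 0.0
        assert s.n_pairs == 3

    def test_quantiles_match_direct_computation(self, rng):
        """Median/IQR agree with a direct type-7 quantile computation on
        the pairwise values the summary itself reports."""
        from okit.synthetic_data import simulate_codon_gene

        seqs = simulate_codon_gene(
            "((A:0.1,B:0.1):0.05,(C:0.1,D:0.15):0.05);", 0.2, 2.0, 120, seed=3
        )
        aln = CodonAlignment(
            gene="g", taxa=sorted(seqs), rows=[seqs[t] for t in sorted(seqs)]
        )
        s = gene_rate_summary(aln)
        vals = np.array(list(s.pairwise_dn.values()))
        assert s.median_dn == pytest.approx(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        assert s.iqr == pytest.approx(q3 - q1)
        assert min(vals) <= s.median_dn <= max(vals)
        assert s.iqr >= 0


class TestCorrelation:
    def _summary(self, gene, med, iqr, length=1200):
        return GeneRateSummary(
            gene=gene, length_nt=length, pairwise_dn={}, median_dn=med, iqr=iqr
        )

    def test_perfectly_linear(self):
        s = [self._summary(f"g{i}", 0.1 * i, 0.05 * i + 0.01) for i in range(1, 6)]
        r, p = rate_iqr_correlation(s)
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        s = [self._summary(f"g{i}", 0.1 * i, -0.05 * i + 0.5) for i in range(1, 6)]
        r, _ = rate_iqr_correlation(s)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        med = rng.random(20)
        iqr = 0.3 * med + rng.random(20) * 0.1
        s = [
            self._summary(f"g{i}", float(m), float(q))
            for i, (m, q) in enumerate(zip(med, iqr))
        ]
        r, _ = rate_iqr_correlation(s)
        expected = float(
            ((med - med.mean()) * (iqr - iqr.mean())).sum()
            / np.sqrt(((med - med.mean()) ** 2).sum() * ((iqr - iqr.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        s = [self._summary(f"g{i}", 0.5, 0.1) for i in range(5)]
        with pytest.raises(ValueError):
            rate_iqr_correlation(s)


class TestFilterCandidates:
    def _summary(self, gene, iqr, length):
        return GeneRateSummary(
            gene=gene, length_nt=length, pairwise_dn={}, median_dn=0.1, iqr=iqr
        )

    def test_short_gene_excluded_by_length(self):
        s = [self._summary("short", 0.01, 800),
             self._summary("a", 0.02, 1200),
             self._summary("b", 0.9, 1200)]
        cands = {c.gene: c for c in filter_candidates(s, iqr_mode="top-k", top_k=1)}
        assert cands["short"].length_excluded and not cands["short"].candidate

    def test_high_iqr_gene_excluded_despite_length(self):
        s = [self._summary("fast", 0.9, 1200),
             self._summary("a", 0.02, 1200),
             self._summary("b", 0.03, 1200)]
        cands = {c.gene: c for c in filter_candidates(s, iqr_mode="top-k", top_k=1)}
        assert cands["fast"].iqr_excluded and not cands["fast"].candidate

    def test_mirrored_candidate_counts(self, rng):
        """170 genes, 27 high-IQR, 101 short among the remainder -> 42
        candidates (the two rules are independent set intersections)."""
        summaries = []
        for i in range(27):
            summaries.append(self._summary(f"hi{i}", 0.5 + 0.01 * i, 1200))
        lengths = [600] * 101 + [1200] * 42
        for i, length in enumerate(lengths):
            summaries.append(self._summary(f"lo{i}", 0.001 * (i % 10), length))
        cands = filter_candidates(summaries, iqr_mode="top-k", top_k=27)
        assert sum(c.candidate for c in cands) == 42

    def test_filter_order_independent(self):
        """Applying IQR-then-length equals length-then-IQR: candidacy is the
        intersection of the two pass sets."""
        rnd = random.Random(2)
        summaries = [
            self._summary(f"g{i}", rnd.random(), rnd.choice([500, 1000, 1500]))
            for i in range(40)
        ]
        cands = filter_candidates(summaries, iqr_mode="top-k", top_k=10)
        iqr_pass = {c.gene for c in cands if not c.iqr_excluded}
        len_pass = {c.gene for c in cands if not c.length_excluded}
        assert {c.gene for c in cands if c.candidate} == iqr_pass & len_pass

    def test_top_bin_mode_assigns_bins(self):
        summaries = [
            self._summary(f"g{i}", iqr, 1200)
            for i, iqr in enumerate([0.01, 0.02, 0.03, 0.3, 0.4, 0.5])
        ]
        cands = filter_candidates(summaries, iqr_mode="top-bin", n_bins=3)
        excluded = {c.gene for c in cands if c.iqr_excluded}
        assert excluded == {"g4", "g5"}
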