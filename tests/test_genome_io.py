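"""Genome parsing and descriptive statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from okit._seq import revcomp
from okit.genome_io import (
    GeneFeature,
    OrganelleGenome,
    codon_usage_summary,
    find_inverted_repeats,
    gc_content,
    noncoding_total,
    parse_genbank,
    quadripartite,
    _span_union_size,
)
from conftest import random_sequence


def _write_record(tmp_path, record, name="test.gb"):
    path = tmp_path / name
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")
    return path


class TestParseGenbank:
    def test_feature_kinds_assigned(self, tmp_path, rng):
        seq = random_sequence(rng, 300)
        record = SeqRecord(
            Seq(seq), id="FIX1", name="FIX1",
            annotations={"molecule_type": "DNA", "organism": "Fixus"},
        )
        record.features = [
            SeqFeature(FeatureLocation(0, 90, strand=1), type="CDS",
                       qualifiers={"gene": ["alpha"]}),
            SeqFeature(FeatureLocation(100, 190, strand=-1), type="CDS",
                       qualifiers={"gene": ["beta"]}),
            SeqFeature(FeatureLocation(200, 270, strand=1), type="tRNA",
                       qualifiers={"gene": ["trnK-uuu"]}),
        ]
        genome = parse_genbank(_write_record(tmp_path, record))[0]
        assert len(genome.features) == 3
        assert [f.kind for f in genome.features] == ["CDS", "CDS", "tRNA"]
        assert genome.features[1].strand == "-"
        assert genome.taxon == "Fixus"

    def test_origin_wrapping_join_unwrapped(self, tmp_path, rng):
        # join(500..660,1..220) on a 660 bp circle: two spans, 161+220=381 nt
        seq = random_sequence(rng, 660)
        record = SeqRecord(
            Seq(seq), id="WRAP1", name="WRAP1",
            annotations={"molecule_type": "DNA", "topology": "circular"},
        )
        loc = CompoundLocation(
            [FeatureLocation(499, 660, strand=1), FeatureLocation(0, 220, strand=1)]
        )
        record.features = [
            SeqFeature(loc, type="CDS", qualifiers={"gene": ["wrapper"]})
        ]
        genome = parse_genbank(_write_record(tmp_path, record))[0]
        (feat,) = genome.features
        assert feat.spans == ((499, 660), (0, 220))
        assert feat.length == 381
        assert genome.feature_sequence(feat) == seq[499:] + seq[:220]

    def test_missing_sequence_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.gb"
        path.write_text(
            "LOCUS       EMPTY         10 bp    DNA     circular PLN 01-JAN-2020\n"
            "DEFINITION  no origin.\nACCESSION   EMPTY\n//\n"
        )
        with pytest.raises(Exception):
            parse_genbank(path)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguity_excluded_from_denominator(self):
        assert gc_content("GCNN") == 100.0

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_invariant_under_reverse_complement(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(10, 200)))
            assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))
            assert 0.0 <= gc_content(seq) <= 100.0


class TestNoncoding:
    def test_fully_covered(self):
        g = OrganelleGenome(
            id="g", taxon="t", sequence="A" * 100,
            features=[GeneFeature("x", "CDS", "+", ((0, 100),))],
        )
        assert noncoding_total(g) == (0, 0.0)

    def test_overlapping_features(self):
        g = OrganelleGenome(
            id="g", taxon="t", sequence="A" * 100,
            features=[
                GeneFeature("x", "CDS", "+", ((0, 60),)),
                GeneFeature("y", "CDS", "+", ((50, 90),)),
            ],
        )
        assert noncoding_total(g) == (10, 10.0)

    def test_union_vs_bruteforce_on_random_intervals(self, rng):
        """Union size + non-coding bp must always equal genome length."""
        for _ in range(30):
            length = int(rng.integers(50, 400))
            spans = []
            for _ in range(int(rng.integers(0, 12))):
                start = int(rng.integers(0, length - 1))
                end = int(rng.integers(start + 1, length + 1))
                spans.append((start, end))
            covered = np.zeros(length, dtype=bool)
            for start, end in spans:
                covered[start:end] = True
            assert _span_union_size(length, spans) == int(covered.sum())


class TestCodonUsage:
    def test_forward_gene(self):
        g = OrganelleGenome(
            id="g", taxon="t", sequence="ATGAAACCCTAA" + "G" * 20,
            features=[GeneFeature("x", "CDS", "+", ((0, 12),))],
        )
        summary = codon_usage_summary(g)
        assert summary.start_counts == {"ATG": 1}
        assert summary.stop_counts == {"TAA": 1}

    def test_reverse_strand_gene(self, toy_genome):
        # geneB forward-strand text TTACATGGGCAT reverse-complements to
        # ATGCCCATGTAA: start ATG, stop TAA.
        summary = codon_usage_summary(toy_genome)
        assert summary.start_counts == {"ATG": 2}
        assert summary.stop_counts == {"TAA": 2}
        assert summary.non_atg_genes == []

    def test_start_and_stop_tallies_balance(self, sim_dataset):
        _, genomes, _ = sim_dataset
        for genome in genomes:
            s = codon_usage_summary(genome)
            n_cds = len(genome.features_of_kind("CDS", "orf")) - len(s.excluded)
            assert sum(s.start_counts.values()) == n_cds
            assert sum(s.stop_counts.values()) == n_cds

    def test_out_of_frame_cds_excluded(self):
        g = OrganelleGenome(
            id="g", taxon="t", sequence="ATGAAACCCTAAG" + "G" * 20,
            features=[GeneFeature("x", "CDS", "+", ((0, 13),))],
        )
        summary = codon_usage_summary(g)
        assert summary.excluded == ["x"]
        assert summary.start_counts == {}


_COMP = str.maketrans("ACGT", "TGCA")


def _bruteforce_best_ir(seq: str, min_len: int):
    """O(n^2) oracle: the longest disjoint (posA, posB, length) pair with
    seq[posA:posA+L] == revcomp(seq[posB:posB+L]) on the linear sequence.

    An inverted-repeat pair is anchored by the left end of one copy and the
    right end of the other (position e-1): it grows inward while
    seq[i+L] is the complement of seq[e-1-L].
    """
    n = len(seq)
    best = None
    for i in range(n):
        for e in range(i + 2, n + 1):
            length = 0
            while i + length < e - length and seq[i + length] == seq[
                e - 1 - length
            ].translate(_COMP):
                length += 1
            if length >= min_len and (best is None or length > best[2]):
                best = (i, e - length, length)
    return best


class TestInvertedRepeats:
    def test_planted_repeat_found(self, rng):
        core = random_sequence(rng, 30)
        seq = (
            random_sequence(rng, 300) + core + random_sequence(rng, 400)
            + revcomp(core) + random_sequence(rng, 270)
        )
        hits = find_inverted_repeats(seq, min_len=25)
        assert hits, "planted 30 bp inverted repeat not found"
        pos_a, pos_b, length = hits[0]
        assert length >= 30
        assert seq[pos_a : pos_a + length] == revcomp(seq[pos_b : pos_b + length])

    def test_repeat_free_sequence_empty(self):
        assert find_inverted_repeats("ACGT" * 30, min_len=60) == []

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(5):
            core = random_sequence(rng, int(rng.integers(22, 40)))
            seq = (
                random_sequence(rng, 60) + core + random_sequence(rng, 80)
                + revcomp(core) + random_sequence(rng, 60)
            )
            expected = _bruteforce_best_ir(seq, 20)
            hits = find_inverted_repeats(seq, min_len=20)
            assert expected is not None and hits
            assert hits[0][2] == expected[2]


class TestQuadripartite:
    def _genome_with_irs(self):
        # 100 bp circle, 10 bp IRs at [0,10) and [40,50): arcs 30 and 50
        rng = np.random.default_rng(3)
        ir = random_sequence(rng, 10)
        seq = ir + random_sequence(rng, 30) + revcomp(ir) + random_sequence(rng, 50)
        return OrganelleGenome(id="q", taxon="t", sequence=seq)

    def test_symmetric_toy_layout(self):
        genome = self._genome_with_irs()
        layout = quadripartite(genome, (0, 40, 10))
        assert layout.ir_len == 10
        assert layout.lsc_len == 50
        assert layout.ssc_len == 30

    def test_adjacent_irs_error(self):
        genome = self._genome_with_irs()
        with pytest.raises(ValueError):
            quadripartite(genome, (0, 10, 10))

    def test_overlapping_irs_error(self):
        genome = self._genome_with_irs()
        with pytest.raises(ValueError):
            quadripartite(genome, (0, 5, 10))
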