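"""Identity scans, divergent regions, spacer nomination, in-silico PCR."""

import numpy as np
import pytest

from okit._seq import revcomp
from okit.divergence_scan import (
    Amplicon,
    CollinearityError,
    IdentityTrack,
    PrimerPair,
    anchored_identity,
    count_polymorphic_sites,
    divergent_regions,
    in_silico_pcr,
    intergenic_spacers,
    merge_intervals,
    spacer_candidates,
)
from okit.genome_io import GeneFeature, OrganelleGenome
from conftest import random_sequence


def _toy_pair(rng, spacer_divergence=0.2):
    """Reference with 4 anchor genes and spacers; query identical except one
    spacer mutated at the given per-site rate."""
    genes = {}
    pos = 0
    parts = []
    feats = []
    layout = [("gA", 300), (None, 200), ("gB", 300), (None, 250),
              ("gC", 300), (None, 200), ("gD", 300), (None, 150)]
    spacer_spans = []
    for name, length in layout:
        seq = random_sequence(rng, length)
        parts.append(seq)
        if name:
            feats.append(GeneFeature(name, "CDS", "+", ((pos, pos + length),)))
        else:
            spacer_spans.append((pos, pos + length))
        pos += length
    ref_seq = "".join(parts)
    ref = OrganelleGenome(id="REF", taxon="ref", sequence=ref_seq, features=feats)

    # mutate the second spacer only
    target = spacer_spans[1]
    q = list(ref_seq)
    for i in range(*target):
        if rng.random() < spacer_divergence:
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
    query = OrganelleGenome(
        id="QRY", taxon="qry", sequence="".join(q), features=feats
    )
    return ref, query, target


class TestAnchoredIdentity:
    def test_self_identity_one_everywhere(self, collinear_dataset):
        _, genomes, _ = collinear_dataset
        track = anchored_identity(genomes[0], genomes[0])
        assert np.all(track.values() == 1.0)

    def test_planted_diverged_spacer_detected(self, rng):
        ref, query, target = _toy_pair(rng)
        track = anchored_identity(ref, query, window=100, step=50)
        in_spacer = [
            ident for ws, we, ident in track.windows
            if ws >= target[0] and we <= target[1]
        ]
        outside = [
            ident for ws, we, ident in track.windows
            if we <= target[0] or ws >= target[1]
        ]
        assert in_spacer and min(outside) > max(in_spacer)
        assert np.mean(in_spacer) == pytest.approx(0.8, abs=0.08)
        assert min(outside) > 0.95

    def test_reverse_complemented_query_handled(self, rng):
        ref, query, _ = _toy_pair(rng, spacer_divergence=0.0)
        n = len(query.sequence)
        flipped_feats = [
            GeneFeature(
                f.name, f.kind, "-" if f.strand == "+" else "+",
                ((n - f.spans[0][1], n - f.spans[0][0]),),
            )
            for f in query.features
        ]
        flipped = OrganelleGenome(
            id="QRYRC", taxon="qryrc", sequence=revcomp(query.sequence),
            features=flipped_feats,
        )
        track = anchored_identity(ref, flipped, window=100, step=100)
        assert track.values().mean() == pytest.approx(1.0)

    def test_too_few_anchors_error(self, rng):
        seq = random_sequence(rng, 500)
        feats = [GeneFeature("only", "CDS", "+", ((0, 90),))]
        g = OrganelleGenome(id="X", taxon="x", sequence=seq, features=feats)
        with pytest.raises(CollinearityError):
            anchored_identity(g, g)

    def test_spacers_rank_below_genes_in_simulation(self, collinear_dataset):
        """Fast-evolving spacers drag window identity below gene windows."""
        _, genomes, _ = collinear_dataset
        ref = genomes[0]
        query = genomes[-1]
        track = anchored_identity(ref, query, window=200, step=200)
        covered = np.zeros(len(ref), dtype=bool)
        for f in ref.features:
            for s, e in f.spans:
                covered[s:e] = True
        gene_idents, spacer_idents = [], []
        for ws, we, ident in track.windows:
            frac = covered[ws:we].mean()
            if frac > 0.9:
                gene_idents.append(ident)
            elif frac < 0.4:
                spacer_idents.append(ident)
        assert np.mean(spacer_idents) < np.mean(gene_idents)


class TestDivergentRegions:
    def _track(self, idents, window=100):
        windows = [
            (i * window, (i + 1) * window, v) for i, v in enumerate(idents)
        ]
        return IdentityTrack(ref_id="R", query_id="Q", windows=windows)

    def test_all_identity_empty(self):
        t = self._track([1.0] * 8)
        assert divergent_regions([t], threshold=0.7) == []

    def test_planted_block_merged(self):
        t = self._track([1, 1, 0.5, 0.5, 0.5, 1, 1, 1])
        regions = divergent_regions([t], threshold=0.7)
        assert regions == [(200, 500)]

    def test_threshold_monotonicity(self, rng):
        idents = rng.random(30)
        t = self._track(list(idents))
        strict = divergent_regions([t], threshold=0.5)
        loose = divergent_regions([t], threshold=0.7)
        covered_strict = {p for s, e in strict for p in range(s, e)}
        covered_loose = {p for s, e in loose for p in range(s, e)}
        assert covered_strict <= covered_loose

    def test_query_fraction_rule(self):
        low = self._track([0.5] * 4)
        high = self._track([0.9] * 4)
        assert divergent_regions([low, high], threshold=0.7,
                                 min_query_fraction=0.6) == []
        assert divergent_regions([low, high], threshold=0.7,
                                 min_query_fraction=0.5) != []

    def test_merge_intervals(self):
        assert merge_intervals([(5, 8), (0, 3), (2, 6)]) == [(0, 8)]


class TestSpacerCandidates:
    def _genome_with_spacers(self, rng, spacer_lengths):
        parts, feats, pos = [], [], 0
        for i, slen in enumerate(spacer_lengths):
            gene = random_sequence(rng, 120)
            feats.append(GeneFeature(f"g{i}", "CDS", "+", ((pos, pos + 120),)))
            parts.append(gene)
            pos += 120
            parts.append(random_sequence(rng, slen))
            pos += slen
        return OrganelleGenome(
            id="S", taxon="s", sequence="".join(parts), features=feats
        )

    def test_length_verdicts(self, rng):
        # spacer lengths mirroring rejected-short, kept, rejected-long cases
        genome = self._genome_with_spacers(rng, [48, 970, 3144, 160, 1433])
        regions = [(0, len(genome))]  # everything divergent
        cands = spacer_candidates(regions, genome, min_len=200, max_len=1400)
        verdicts = {c.length: c.verdict for c in cands}
        assert verdicts[48] == "too_short"
        assert verdicts[160] == "too_short"
        assert verdicts[970] == "kept"
        assert verdicts[1433] == "too_long"
        assert verdicts[3144] == "too_long"

    def test_only_overlapping_spacers_reported(self, rng):
        genome = self._genome_with_spacers(rng, [300, 300, 300])
        spacers = intergenic_spacers(genome)
        first = spacers[0]
        cands = spacer_candidates([(first[0], first[1])], genome)
        assert len(cands) == 1
        assert cands[0].flanking == ("g0", "g1")


class TestPolymorphicSites:
    def test_identical_rows_zero(self):
        assert count_polymorphic_sites(["ACGT", "ACGT"])[0] == 0

    def test_positions_reported(self):
        rows = [
            "A" * 1000,
            "A" * 10 + "C" + "A" * 989,
            "A" * 250 + "G" + "A" * 749,
            "A" * 600 + "T" + "A" * 150 + "C" + "A" * 248,
        ]
        count, positions, gapped = count_polymorphic_sites(rows)
        assert count == 4
        assert positions == [10, 250, 600, 751]
        assert gapped == []

    def test_gap_column_excluded_but_reported(self):
        rows = ["AAC", "A-G", "AAG"]
        count, positions, gapped = count_polymorphic_sites(rows)
        assert count == 1 and positions == [2]
        assert gapped == [1]

    def test_invariant_under_row_reordering(self, rng):
        rows = ["ACGTAC", "ACCTAC", "AGGTAC"]
        a = count_polymorphic_sites(rows)
        b = count_polymorphic_sites(rows[::-1])
        assert a == b

    def test_ragged_alignment_error(self):
        with pytest.raises(ValueError):
            count_polymorphic_sites(["ACGT", "ACG"])


class TestInSilicoPcr:
    def _planted(self, rng, product=970):
        seq = random_sequence(rng, 10_000)
        fwd = seq[2000:2021]
        rev = revcomp(seq[2000 + product - 22 : 2000 + product])
        return seq, PrimerPair(forward=fwd, reverse=rev)

    def test_planted_pair_single_amplicon(self, rng):
        seq, primers = self._planted(rng)
        amps = in_silico_pcr(seq, primers)
        assert len(amps) == 1
        assert amps[0].length == 970
        assert amps[0].start == 2000

    def test_no_binding_site_empty(self, rng):
        seq = random_sequence(rng, 3000)
        primers = PrimerPair(forward="A" * 20, reverse="C" * 20)
        if "A" * 20 not in seq and "G" * 20 not in seq:
            assert in_silico_pcr(seq, primers) == []

    def test_reverse_complement_genome_mirrors_amplicon(self, rng):
        seq, primers = self._planted(rng)
        fwd_amps = in_silico_pcr(seq, primers)
        rc_amps = in_silico_pcr(revcomp(seq), primers)
        assert len(rc_amps) == len(fwd_amps) == 1
        a, b = fwd_amps[0], rc_amps[0]
        assert b.length == a.length
        assert b.strand != a.strand
        assert b.start == len(seq) - a.end

    def test_origin_wrapping_product(self, rng):
        seq, primers = self._planted(rng)
        rotated = seq[2500:] + seq[:2500]  # forward site now wraps
        amps = in_silico_pcr(rotated, primers)
        assert len(amps) == 1
        assert amps[0].length == 970

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair(forward="ACGTACGTAC", reverse="ACGTACGTACGTACG")

    def test_three_prime_mismatch_blocks_binding(self, rng):
        seq, primers = self._planted(rng)
        bad_fwd = primers.forward[:-1] + (
            "A" if primers.forward[-1] != "A" else "C"
        )
        bad = PrimerPair(forward=bad_fwd, reverse=primers.reverse)
        assert in_silico_pcr(seq, bad, max_mismatch=1) == []
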