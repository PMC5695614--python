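# Methods

This note documents the models, conventions and numerical choices behind
`okit`, and what the simulated-truth validation does and does not show.

## Coordinates and genome representation

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted at the parsing boundary.  Genomes are
circular: an origin-spanning `join` location becomes a multi-span feature
whose total length feeds every statistic.  A feature's sequence is the
concatenation of its spans, reverse complemented as a whole on the minus
strand.  Translation tables default to NCBI table 11 for plastids and
table 1 for mitochondria (TGA then counts as a stop in codon tallies);
both are per-genome configurable.  The "coding" union for the non-coding
total covers all CDS + tRNA + rRNA + orf spans; introns inside annotated
gene spans count as coding, a convention the statistics report makes
explicit because annotation practice varies.

Protein-coding gene counts are reported two ways (`n_cds` and
`n_cds_plus_orf`) because deposited records are inconsistent about
whether conserved orfs count as protein-coding genes; the toolkit reports
both rather than guessing a convention.

## Inverted repeats and the quadripartite layout

IR detection is exact-match seed-and-extend on the circular sequence
(20-mer seeds, maximal bidirectional extension, disjointness required).
Exact matching is the default because the question is the annotated IR
length; a mismatch allowance would require an arbitrary scoring choice
and the detector is cross-checked against an O(n²) brute-force oracle in
the tests instead.  The two arcs between the IR copies are labelled LSC
(longer) and SSC (shorter); adjacent or overlapping copies are an error
rather than a degenerate layout.

## Gene-content harmonization and Dollo mapping

Name matching is case-insensitive; tRNA names are normalized to
`trnX(anticodon)`.  A small curated synonym table maps common alternate
names (e.g. `psb28` → `psbW`); unresolved names pass through and are
reported, because silently dropping them would bias presence matrices.
Sequence-similarity rescue of differently-named hypothetical proteins is
out of scope: harmonization is name-based, user-extensible via a
two-column TSV.

Dollo mapping places each gene's single gain on the branch above the MRCA
of its bearers and one loss above each maximal all-absent subtree below
it.  This minimises events under the single-gain constraint (verified
against exhaustive enumeration over all presence patterns on 6-leaf
trees).  The "ancestral core" utility counts genes whose gain maps to the
root given an explicit outgroup presence column — outgroup presence is
supplied as data, never inferred.

## DCJ distance

Genomes are encoded as circular signed orders of the single-copy
CDS/rRNA/orf markers shared by the pair (IR-duplicated genes drop out
automatically).  The distance is *d* = *N* − (*C* + *I*/2) from the
adjacency graph over marker extremities; for two single circular
chromosomes the odd-path term is structurally zero but kept for
generality.  The implementation is validated against a bidirectional
breadth-first search over genome states — an oracle that knows nothing of
the formula — exhaustively for ≤ 5 markers and on random 6–8-marker
pairs, and the metric axioms and invariances (rotation, whole-genome
strand flip, collinear-run collapsing) are property-tested.  Multi-
chromosome genomes and duplicated-marker variants are out of scope.

## NG86 rates and the marker filter

Sites: per sense codon, synonymous sites = (1/3) × (number of the 9
single-nucleotide mutants coding the same amino acid); mutants creating a
stop are excluded from the synonymous tally (one of several NG86
conventions; chosen because it keeps the site counts enumerable and is
applied consistently to the difference counts).  Differences between two
codons are averaged equally over all minimal mutational paths, skipping
paths through stops; if every path is blocked the codon pair contributes
nothing.  Gapped or ambiguous codon columns are excluded pairwise.
*dN* = −(3/4)·ln(1 − (4/3)·*pN*); *pN* ≥ 3/4 is reported as a saturated
(missing) value, and a gene with more than half its pairs saturated is
flagged unusable.  NG86 was chosen over counting schemes without an
enumerable oracle precisely so an independent implementation can verify
every value; the estimator sits behind a single function and is
replaceable.

Quantiles use linear interpolation (numpy default, type 7); the IQR
depends on this choice, so it is fixed and stated.  The high-IQR
exclusion has two modes: `top-bin` (highest bin of an n-quantile split,
default 3) and `top-k` (drop exactly the k highest-IQR genes).  The
filter then removes genes with alignments < 900 nt — short amplicons are
impractical for primer design and carry little signal.  The two rules are
independent set memberships, so filter order cannot change the result
(asserted in tests).

Codon alignments are protein-guided: proteins aligned (mafft when input
lengths differ; the identity alignment when they are already equal-length,
as for simulated genes), then each residue expanded back to its source
codon, terminal stops stripped.

## Trees and congruence

Tree inference is neighbor joining on model-corrected distances (JC for
nucleotides, Poisson for amino acids, raw p-distance available) with
nonparametric bootstrap (column resampling, default 100 replicates,
seed mandatory).  This is deliberately not a likelihood method: the
toolkit's congruence statistics consume *any* Newick trees, so externally
computed ML trees drop in at every point where a tree is used.  Saturated
distances are capped at 5.0 substitutions/site with the cap noted;
negative NJ branch lengths are clamped to zero.

Congruence uses unrooted, label-set-based bipartitions: for each internal
bipartition of the reference tree, the number of gene trees containing
the same split with support ≥ the threshold (default 50%).  Gene trees
missing taxa are handled by restricting the reference split to the gene's
taxon set and discarding splits that become trivial.  Bipartition
containment is invariant to rotation and rooting (tested).

## Divergence scan, spacers, PCR

The identity scan assumes largely collinear genomes: shared single-copy
genes anchor the map (the query is reverse complemented when its anchor
chain runs backwards; a non-collinear chain is an error that points to
the rearrangement module).  Inter-anchor segments are globally aligned
(edlib); identity per window = matches / alignment columns, with
insertion columns charged to the reference position on their left —
indels count against identity.  Windows are 500 bp at 100 bp steps by
default: fine enough to resolve sub-kilobase spacers, coarse enough that
window identity is stable.  Divergent regions merge adjacent windows
below the identity threshold (default 0.7) in at least half the queries.

Spacer candidates are intergenic spans overlapping divergent regions,
with verdicts from length bounds (default 200–1400 bp) chosen so that
regions too short for primer placement or too long for a single Sanger
read are excluded; both bounds are configurable.  Polymorphic sites are
columns with ≥ 2 distinct non-gap states; gap-containing columns are
excluded from the count but reported.  In-silico PCR matches the forward
primer on either strand and the reverse primer on the opposite strand
downstream within a maximum product length, on the doubled sequence so
origin-wrapping products are found; by default no mismatches are
tolerated and the 3'-terminal 5 nt must always match exactly.  Both the
full amplicon length and the primer positions are reported, since
"marker length" may mean either the amplicon or the trimmed insert.

## The simulator

The simulator emits the study conditions every stage is validated under:
eight taxa on a fixed rooted tree mirroring three nested ordinal clades
plus a divergent outgroup, 170 protein-coding genes of 60–600 codons
(straddling the 900 nt marker rule), three rRNAs, and one intergenic
spacer per gene (100–500 bp).

* **Codon evolution** is a discrete M0-like scheme: per branch, proposal
  events arrive as a Poisson process (branch length = expected proposals
  per site), targets drawn with transition bias κ = 2; stop-creating
  proposals are rejected, synonymous ones accepted, nonsynonymous ones
  accepted with probability ω — so ω is the planted dN/dS.  Most genes
  draw ω uniformly in [0.05, 0.2]; 16% are "erratic" with ω = 0.5 and a
  per-branch rate multiplier that flips between 0.1× and 8× (a two-regime
  heterotachy; an earlier lognormal-multiplier scheme could draw tame
  multipliers and leave a planted 'erratic' gene statistically ordinary,
  making the label unverifiable).  First and last codons are protected so
  frames stay annotatable.
* **Gene content**: losses are Dollo-style with per-gene-per-branch
  probability 0.02 by default; a gene is lost at most once and never on a
  branch incident to the root, so every planted event is identifiable by
  Dollo reconstruction (a root-adjacent loss is indistinguishable from
  "never gained").  Lineage-specific orf gains occur on terminal branches
  (probability 0.25 per branch by default).
* **Rearrangements** are inversions of gene-bounded circular segments
  (1 to n−1 genes, never the whole circle), one per branch by default —
  each operation is a DCJ operation, and the applied counts are the truth
  the estimated distances are compared against.
* **Spacers** evolve 4× faster than genes with geometric-length indels
  (so identity scans face realistic gaps); genes evolve without indels,
  keeping their true codon alignments trivial; rRNAs evolve indel-free at
  0.3×.  Base composition is AT-rich (70% AT) as in organelle genomes.

Everything is drawn from one seeded generator in a fixed traversal
order, so identical seed + config give byte-identical GenBank output.

**What passing does and does not show.**  The simulator plants exactly
the structures the methods estimate — single-copy markers, indel-free
genes, identifiable losses, collinear spacer datasets.  Passing therefore
shows the estimators are correct on their own model, not that real
annotations are clean: real data bring annotation errors, paralogy,
IR-boundary ambiguity, alignment uncertainty and saturation, which enter
through the harmonization report, the saturation flags and the
alignment-import paths rather than through these tests.

## Problem sizes and determinism

The validation study uses the full 170-gene, 8-taxon scale for the rates
and content stages; rearrangement recovery uses 100 replicate 50-marker
genomes; rank-concordance uses 250-codon genes across 30–40 replicate
seeds; congruence uses six 500-codon genes on a long-branch tree; the
exhaustive DCJ check covers all signed circular permutations of ≤ 5
markers plus 100 random 6–8-marker pairs.  These sizes keep the whole
suite and the acceptance script within a few minutes on one CPU while
leaving every estimator at (or above) the scale it is used at in the
analyses.  Pipeline reports exclude wall-clock timing (kept in a separate
log) so reruns at one seed are byte-identical, which is itself asserted.

## Known limitations

* Harmonization is name-based; differently-named homologs without a
  synonym entry fragment the presence matrix.
* The DCJ encoding drops IR-duplicated and multi-copy genes; distances
  over heavily duplicated genomes are therefore over a reduced marker
  set, and rearrangement scenarios (sorting sequences) are not produced.
* NG86 is a counting estimator: it underestimates rates under strong
  codon usage bias or saturation relative to ML codon models.
* NJ + bootstrap is a stand-in for likelihood inference; for publication
  phylogenies, import externally computed trees.
* The identity scan requires ≥ 3 shared single-copy anchors and a
  collinear anchor chain; rearranged genomes must go through the DCJ
  module instead.
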