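# Methods

This note documents the models, estimators, and design choices behind
each analysis stage, the semantics of the synthetic-data generator, and
the limits of what the synthetic checks demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open; 1-based inclusive
conversion happens only when reading/writing GFF3/GTF/MAF.  A splice
junction is identified by its intron `(seq_id, donor, acceptor, strand)`
with donor < acceptor in genomic order; matching of counts to events
ignores strand, since the genomic footprint of an intron is unique.
Sequences are stored as DNA; motif patterns written in RNA (U) are
converted on input.  Multi-species alignment blocks are normalised to
reference-forward orientation on reading; each block carries a bijective
map between ungapped reference positions and alignment columns.

## Event catalog

Each transcript is subdivided into exon trios; isoform comparison within
a gene types the middle exon:

- **cassette** — the skip junction (C1 end → C2 start) exists in another
  isoform; inclusion junctions C1A and AC2, exclusion C1C2.
- **multi-cassette** — a run of ≥2 consecutive internal exons with a
  single full-skip junction; inclusion support uses only the two
  outermost junctions (C1→A_first, A_last→C2), the minimal unambiguous
  choice when interior junctions are shared with other events.
- **alt 5'/3' splice site** — two isoforms' middle exons share one
  boundary and differ at the other; the alternative region is the
  extension, inclusion junctions are the shared adjacent junction plus
  the extended-variant junction, exclusion is the short-variant
  junction.  The type follows from which end varies in *transcription*
  direction (donor vs acceptor), so the same genomic configuration is
  alt5 on the + strand and alt3 on the −.
- **mutually exclusive** — two disjoint middle exons with shared flanks
  that never co-occur in any isoform; PSI is defined as inclusion of the
  genomically 5' exon (a fixed convention so values are comparable).

Events with identical junction sets collapse to one record; ids are
assigned after a deterministic genomic sort, so the catalog is
reproducible and idempotent.  Intron retention and alternative
first/last exons are out of scope.

## PSI and differential calls

    PSI = 100 · ½(ΣCiA + ΣACj) / [ ½(ΣCiA + ΣACj) + ΣCiCj ]

For mutually exclusive events the exclusion form also spans two
junctions, so its sum is halved as well; otherwise the estimator would
be biased toward skipping by a factor of two in read support.  PSI is
undefined (missing) when all junction counts are zero.

Testability requires ≥10 combined reads over both splice forms in each
sample, and, for cassette and mutually exclusive events, at most a
30-fold ratio between the two adjacent inclusion junctions in each
sample (a ratio of exactly 30 passes; zero against nonzero counts as
infinite imbalance; zero against zero leaves balance undefined and
passes, the read-support filter governs such events).  The "combined 10
reads" rule is enforced per sample — the stricter reading — and the
output metadata records it.

The call tests the 2×2 table [[inclusion_wt, exclusion_wt],
[inclusion_mut, exclusion_mut]] of **unhalved** integer read sums with a
2-sided Fisher exact test: an exact test needs integer cells, and
halving both inclusion entries would not change the odds ratio.  A call
requires p < α (default 0.05, uncorrected, matching the screening
design; a Benjamini–Hochberg option exists for reuse) and |ΔPSI| ≥ 15
(inclusive).  Mutant-vs-mutant comparisons use the upper-tail
hypergeometric overlap test and Pearson correlation of PSI over shared
events (≥3 defined pairs required).

Replicate pooling is the caller's responsibility: one count table per
condition is accepted, and pooling lanes before testing is the
documented convention.

## Splice-proximal regions and conserved motifs

Seven region labels per event, all in transcription orientation and all
≤300 nt from their anchoring splice site: the alternative exon (whole
exon if ≤600 nt, else its two proximal 300-nt slices), the 5'- and
3'-proximal sub-regions of each flanking intron (introns shorter than
600 nt split at the midpoint so the sub-regions stay disjoint), and up
to 300 nt of each flanking constitutive exon, clipped to the exon so
hits never straddle a splice site.  Sequences are sense-strand; a motif
must fit entirely inside a region to count.

Motif patterns accept IUPAC codes and parenthesised alternations; all
overlapping occurrences are reported.  Conservation of an occurrence is
assessed in alignment-column space — the only coordinate system shared
between species: a species supports an occurrence if it has an exact
match whose sense-start column lies within ±25 columns of the reference
sense-start column, within the same alignment block (blocks delimit
orthology; cross-block matches are ignored).  Conserved ⇔ ≥2 supporting
species.  An occurrence not covered by any block has support 0 and is
flagged "unaligned".

A boundary caveat: column distances between positions on opposite sides
of an inserted gap column change by the insertion width, so a match
sitting exactly at the 25-column limit can legitimately flip when
indels are introduced between it and the anchor.  Away from that
boundary, conservation calls are invariant to pure-gap columns.

## Enrichment, co-occurrence and composition controls

Controls for motif enrichment are drawn from the alternatively spliced
background (wild-type PSI within 5–95), binned in 5-percentage-point PSI
bins; each of 100 control sets matches the cases' per-bin counts,
sampling without replacement within a set (nearest non-empty bin as
fallback).  The case proportion of events with ≥1 qualifying occurrence
is compared to the control sets with a one-sided Fisher test; by
default the control cell counts are the rounded means across sets
("averaged" mode; "pooled" mode uses the union).  The region policy is
flanking introns only, or introns + alternative exon for factors (like
MEC-8) whose sites act from exons; calls can be restricted by direction
(increased inclusion vs skipping).

Co-occurrence of two motifs in one event set: presence/absence per event
(multiple instances count once) in the flanking introns; expected count
N·(n_a/N)·(n_b/N); p = P(X ≥ obs) for X ~ Hypergeom(N, n_a, n_b) — the
standard overlap formulation consistent with the multiplicative
expectation.  Two controls accompany it: per-dinucleotide Mann–Whitney
comparisons of region composition (16 overlapping-dinucleotide
frequencies, denominator length−1), and functional-term enrichment where
each term's gene set is compared to 1000 random gene sets matched on
total intron length (10 quantile bins), alongside a plain hypergeometric
term test over the gene universe.

## Spacing and ordering of motif pairs

Spacing is measured within one intronic sub-region: among all cross
pairs of instances, the pair with the smallest non-negative gap (end of
upstream motif to start of downstream motif) is taken; overlapping
instances carry no spacing, and a pair whose instances only overlap
yields no record.  Per other species, all cross pairs of matches in the
columns of that region are enumerated and the spacing most similar to
the reference is kept; the pair is spacing-conserved when ≥2 species are
within ±20% (a reference spacing of 0 requires exactly 0).

Ordering considers both motifs anywhere in the two flanking introns.
The closest instance pair fixes the reference order (ties at identical
starts are dropped); each other species with both motifs within ±25
columns of the respective reference instances — in the same block —
contributes one preserved/reversed observation.  The pair-level
statistic is our own construction (documented and swappable): a
chi-squared test of preserved:reversed against 50:50 over all
(event, species) observations decides order conservation (α = 0.05,
requiring preserved > reversed and ≥3 contributing events); conserved
pairs are unidirectional when a two-sided binomial test rejects 50:50
on the per-event reference orders, else bidirectional.  Relative
positions of one motif around an anchor motif use the same closest-pair
instances, with a two-sided sign binomial test (zero offsets excluded
and reported separately).

## Fitness interactions

Within each experiment, technical replicates are averaged first;
relative fitness w(s, r) divides the RNAi-condition mean by the
control-RNAi mean of the same strain.  Expected double-perturbation
fitness is multiplicative — w(WT, r) × m, with m the mutant/WT ratio of
control means — and the observed/expected score algebraically reduces to
w(mut, r)/w(WT, r), making it invariant to any per-experiment rescaling
of populations.  The overall score is the mean across experiments.

Significance uses a Welch two-sample t-test of per-experiment log scores
against the control-RNAi log scores.  Because the score of the control
RNAi is identically 1 by construction when computed from replicate
means, the comparison numerically equals a one-sample test of the log
score against 0; both samples constant and equal yields p = 1.  Screen
hits are pairs with mean score strictly below 0.7; sister alleles of one
factor can be declared as a strain class and average into a single pair
score.  TOF/EXT worm-size metrics are passed through as per-condition
means only.

## Synthetic-data generator

The generator emulates the study's inputs at desk scale with exact
ground truth.  Defaults: 60 genes (4–7 exons of 100–220 nt, log-normal
introns with median 500 nt and a 320-nt floor), half the genes carrying
a cassette exon; one wild-type and one mutant sample; half the cassette
events differential with |ΔPSI| = 40 (wild-type PSI uniform in 20–60,
direction random), the rest with equal PSI uniform in 5–95; sequencing
depth 100 reads per junction.

Junction counts: C1A ~ Binom(D, p), AC2 ~ Binom(D, p) independently and
C1C2 ~ Binom(D, 1−p) — each junction is an independent read-out of the
isoform mixture, which is exactly the regime in which the half-weighted
PSI estimator is consistent.  Constitutive junctions receive Poisson(D)
counts.

Alignments: one block per differential event spanning the whole event.
Non-reference species diverge by per-base substitutions (rate 0.10) and
species-side deletions (rate 0.02, geometric length, mean 2); insertions
relative to the reference are not modelled, so the reference row stays
gap-free and planted coordinates exact.  Each planted motif (default: a
FOX1 GCAUG / MEC8 GCACA pair, 30 nt apart, FOX1 upstream, in the
downstream-intron 5' sub-region of every differential event) names k
carrier species (default 3) which receive an exact copy at a jittered
column (±5 by default, same shift for both members of a
spacing-conserved pair); all chance matches of planted patterns are
scrubbed from the reference event span before planting and ablated from
non-carrier species afterwards, so planted conservation level, spacing
and order are exact by construction, not merely in expectation.
Mutation-free zones around plants make the divergence slightly
non-uniform there; this is the price of exact truth control.

Fitness plates: population(strain, RNAi, rep) = baseline × strain
effect × RNAi effect × epistasis × log-normal noise (sd 0.1), with
epistasis fixed at 1 for the reference strain and the control RNAi;
default 8 technical replicates × 4 experiments, planted epistasis 0.5
for one (mutant, RNAi) pair.

All randomness flows from one seed through named substreams per stage,
so bundles are byte-identical across reruns.  What the generator does
*not* emulate: read-level errors and mapping artefacts, expression
variation between genes, overlapping genes, alignment errors,
insertions, lineage-specific rate variation, or motif occurrences in
secondary-structure context.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on data
matching the model's assumptions — not robustness to mapping or
alignment artefacts in real data.

## Numerical choices and check sizes

Exact tests come from scipy.stats (fisher_exact, hypergeom, binomtest,
chisquare, mannwhitneyu, ttest_ind, pearsonr); cross-checks against
exhaustive enumeration cover every 2×2 table and hypergeometric
parameter set with N ≤ 12.  Calibration and power of the differential
caller use 500 simulated events (null at depth 100, ΔPSI 40 at depth
200) plus exact enumeration of the joint binomial read-sum distribution
at depth 12 (pmf pruning at 1e-10).  Conservation scanning is checked
against a brute-force all-windows scan on 1000 random blocks.
Co-occurrence calibration draws 500 presence/absence catalogs of 1000
events (marginal 0.4) — large enough that the discrete hypergeometric
p-value distribution is dense for a KS uniformity test — and the
dependence case fixes P(both) = 5·p² at marginals 0.2.  Interaction
recovery uses 500 noisy plates (8 × 4 design).  The end-to-end
demonstration runs a 20-gene study through all eight stages twice and
compares sha256 checksums.
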