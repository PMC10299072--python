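# Methods

This note records the models, estimators, numerical conventions and design
choices behind `mitocomp`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and strand conventions

Internally every genome is a linearized majority-strand (J) string with
0-based half-open feature intervals; GenBank's 1-based inclusive
convention exists only at the I/O boundary. A feature with `end <= start`
spans the origin and is read across the junction. Positions are
normalized modulo the genome length; the linearization anchor (default
`cox1`) is cosmetic — all order-level outputs are rotation-invariant, and
`rotate_to_anchor` re-cuts the circle without changing any gene sequence.
Full-genome composition is reported on the J strand (this is what makes
the AT skew negative and the GC skew positive for salticid-like genomes);
per-gene statistics use each gene's own reading orientation, with N-strand
genes reverse-complemented. Ambiguity codes other than N are rejected;
N sites are excluded from every denominator.

Gene names are normalized through a packaged synonym table
(`data/gene_synonyms.tsv`); Leu/Ser tRNA isoforms are resolved from an
anticodon or codon-family qualifier and an unresolvable label is an error,
not a guess. When no control region is annotated, the gap between `trnQ`
and `trnM` (its conserved location in these genomes) is labeled CR; a CR
shorter than a configurable minimum (default 100 bp) is flagged
(`W-CR-SHORT`) rather than suppressed, because partial control regions are
common in deposited records.

## Codon-usage statistics

Counting uses the invertebrate mitochondrial code (NCBI table 5; AGA/AGG =
Ser, ATA = Met, TGA = Trp, stops TAA/TAG, hence 62 sense codons). Stop
codons and N-containing codons are tallied outside the 62-codon table.
The synonymous-family partition is always derived from the translation
table at run time — table 5 has an 8-fold Ser family and no 3-fold family,
so a hard-coded standard-code layout would be wrong.

ENC is Wright's estimator generalized to that partition: per family with
n ≥ 2 observations, F = (nΣp² − 1)/(n − 1); F̄_k averages the defined,
positive F values in each family-size class; ENC = Σ_k n_k/F̄_k capped at
62. Families observed once contribute no F (the estimator is undefined at
n = 1, and treating them as F = 1 would bias ENC down). A size class with
no defined mean is imputed by the 1/k-scaled average of the defined
classes. Fewer than 100 total codons flags the value low-confidence.

GC3 is the G+C fraction over **all** third positions of sense codons, not
synonymously variable sites only — the plain reading of "GC content in the
third codon positions". The neutrality fit is ordinary least squares of
GC12 on GC3 across genomes with Pearson r and its two-sided t-test
p-value; the slope is reported as the mutational share and 1 − slope as
the selective share, the standard reading of the neutrality plot.

## Diversity and distances

π is the mean proportion of differing sites over all unordered pairs.
The default deletion policy is *complete* (columns containing any gap or N
in any taxon are removed before comparison, the DnaSP-style default);
*pairwise* deletion is available by flag, and the invariant π = mean
pairwise p-distance is tested under matching policies. Sliding windows
default to 100 bp with a 25 bp step; windows start at every step multiple
with a final off-step window appended (and flagged) when the alignment
length minus the window is not a step multiple.

Distances: p, JC69, K2P and TN93 by their closed forms from the
transition/transversion partition. "MCL-composite" is a composite-
likelihood-style reading of distance estimation with shared rate
parameters: base frequencies and the split of differences into the two
transition types and transversions are estimated once from counts pooled
over all pairs, and the TN93 closed form is then applied per pair with its
own total difference proportion divided in the pooled ratios. Exact
third-party internals of composite-likelihood distances are not public, so
this is documented as the package's own definition; it converges to TN93
as pairs become homogeneous and to p as p → 0. A non-positive logarithm
argument marks the pair saturated (NaN) — never silently clamped — and
mean distances are emitted both excluding and propagating saturated pairs.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
count, at each position, the synonymous proportion of the three possible
changes excluding changes to stop codons from the denominator, so
S + N = 3 per codon exactly; multi-hit codons average synonymous and
nonsynonymous differences with equal weight over all orderings of the
changed positions, skipping orderings that pass through a stop (if every
ordering does, the steps count as nonsynonymous); pS and pN receive the
Jukes–Cantor correction; the ratio is undefined (not zero) when Ks = 0.
A terminal stop codon is dropped; an internal stop raises an error naming
the codon. The implementation is cross-checked in the tests against
Biopython's independent NG86 estimator (agreement to a few percent; the
residual difference is the stop-codon site convention).

Neighbor joining is the standard Q-criterion agglomeration with negative
branch lengths clamped to zero and ties broken by taxon-label order, so
the tree is a deterministic function of the matrix; topology is
cross-checked against scikit-bio. This is deliberately a sanity-level
tree, not a substitute for likelihood or Bayesian inference.

## Gene order and TDRL

Rearrangement calls are derived from the longest common circular
subsequence between the observed and reference orders (the best rotation
maximizing an O(n²) LCS; ties resolve to a deterministic reconstruction).
Excluded genes form moved blocks by adjacency in the observed order.
A block of tRNAs that did not pass over any PCG or rRNA is a *shuffle*, a
tRNA block that did is a *translocation*, a block containing a PCG or
rRNA is a *PCG move*, and any strand flip — moved or in place — is an
*inversion*. The packaged reference order encodes the conserved
salticid-like arrangement (CR between trnQ and trnM, rrnL between trnL1
and trnV, rrnS between trnV and trnQ, trnN adjacent to trnL2, nine PCGs
plus thirteen tRNAs on the J strand); it is data, not code, and any
reference can be supplied.

The TDRL event bound uses the run-counting characterization: one event
duplicates a window and keeps each gene in exactly one copy, so the
survivors of the first copy (in order) precede the survivors of the
second copy (in order). Applied to a sequence with r maximal ascending
runs this yields at most 2r runs, and conversely a permutation with r
runs is reachable in ⌈log₂ r⌉ events; a single event produces exactly the
permutations with at most one descent inside the window. The bound
minimizes r over all circular relinearizations (both the observed cut and
the reference numbering cut), is 0 exactly for circularly equal orders,
and is verified in the tests against an exhaustive enumeration of all
single-event products for n ≤ 8. A Dilworth-style count of increasing
*subsequences* would be wrong here: an interleaving such as (1,0,3,2) is
covered by two increasing subsequences yet needs two events, because loss
after duplication cannot interleave the two survivor sets. The control
region participates in ordering but never in the TDRL permutation, since
CR movement is a different phenomenon from gene rearrangement.

## Tandem repeats

The detector scans candidate periods (default 5 up to half the sequence),
anchors an array where two consecutive period-length windows agree at
≥ 80% identity, hill-climbs the anchor while the two-window agreement
strictly improves (a window overlapping the flank can otherwise anchor up
to ⌊0.2·period⌋ early), grows the array against a rolling column-majority
consensus, and finally extends exact-match partial copies at both ends.
Hits need ≥ 1.9 copies, ≥ 80% identity and a score of ≥ 50 under
match +2 / mismatch −7 weights — the familiar tandem-repeat-finder
defaults, which in AT-rich control regions are what keeps chance
dinucleotide-scale matches out of the report. Overlapping hits resolve by
score, then smaller period; a consensus that is itself a perfect
repetition of a shorter motif is reduced to the smallest consistent
period, so a 24-bp repeat is never reported as its 48-bp harmonic.
Reported partial-copy lengths are positional facts about the detected
phase: a leading partial that is an exact motif suffix is absorbed into a
rotated consensus, which moves length between the leading and trailing
partials without changing span, period or copy number.

## The synthetic generator

The generator emulates the *statistical* structure of a salticid
mitogenome, not its biology: 13 PCGs with realistic lengths (≈ 3,630
codons in total), valid starts, TAA stops with configurable T/TA
truncations, 22 tRNAs (62–70 nt), two rRNAs, and a CR between trnQ and
trnM; 9 PCGs + 13 tRNAs on the J strand and 4 PCGs + 9 tRNAs + both
rRNAs on the N strand. Defaults are the salticid-like study conditions:
AT content 0.73, AT skew −0.15, GC skew 0.36, GC3 0.15, a 24-nt CR repeat
with five full copies and 22/9-nt partials, and divergence at ω = 0.1,
κ = 2 over 13 taxa.

Codon sampling weights each codon by the product of J-strand target base
frequencies over its three positions (complemented for N-strand genes),
sharpened by a concentration exponent that sets the expected ENC; the
amino-acid profile is a mix of an AT-rich and a GC-rich profile solved —
exactly, since the expectation is linear in the mix — to hit a requested
GC12. Giving the coding third positions the J-strand skews is what makes
the full-genome composition targets reachable at all (the non-coding
quarter of the genome cannot carry the whole skew) and mirrors the real
mechanism, strand-asymmetric mutation pressure; it also makes UUA the top
codon, as observed in these spiders. Non-coding regions are then drawn
from an exact base multiset that compensates the realized coding
composition, so full-genome targets are met to well within ±0.01.
`generate_genome_grid` spans a GC3 grid with GC12 = intercept +
coupling·GC3 (defaults: the observed salticid ranges and coupling 0.249),
giving the neutrality regression a known generating slope.

Divergence is simulated by acceptance/rejection at the codon level: a
proposal picks a uniform site and a κ-weighted alternative base; stop
proposals are discarded; synonymous proposals are accepted at rate 1 and
nonsynonymous at ω (scaled for ω > 1); accepted counts are Poisson with
mean branch-length × sites. This is deliberately not a rate-matrix
exponential — it is simple, auditable, and sufficient for NG86 recovery.
Two caveats are measured facts, not bugs: NG86 under κ = 2 recovers ω
with a small downward bias (≈ 0.16 at ω = 0.2 for the pair mean at
10,000 codons — transition-enriched synonymous opportunity that the
unweighted NG86 site counts do not see), and multi-hit codons can route a
pathway through a nonsynonymous intermediate, so "synonymous-only"
evolution gives Ka ≈ 0 rather than exactly 0 once codons are hit twice.

What passing synthetic tests shows: the estimators recover known
parameters from data with the right marginal structure, at the stated
sizes. What they do not show: robustness to annotation errors, alignment
error, indels, tRNA structure, selection on codon usage beyond the
concentration knob, or among-site rate variation — none of which the
generator emulates.

## Problem sizes and determinism

Tests and the acceptance script run on one synthetic genome (~14.9 kb,
~3,630 codons) or small sets of them: Ka/Ks recovery uses 10,000 codons
and 6 star-tree tips (15 pairs), the neutrality grid 13 genomes, the
TDRL enumeration all permutations for n ≤ 6 plus all single-event
products for n = 7, 8, and the repeat oracle strings of ≤ 200 nt. These
sizes were chosen to give each estimator comfortable statistical margin
while keeping any single check in the seconds range. Every stochastic
step flows from one integer seed through `numpy.random.default_rng`;
fixed seed means byte-identical GenBank, TSV and JSON outputs (GenBank
records carry a fixed date stamp for this reason).
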