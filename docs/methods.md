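# Methods

This note documents the statistical procedures `rnasig` implements, the
conventions and defaults it fixes where several choices were defensible, and
what its synthetic data can and cannot establish.

## Sequences and regions

Sequences are normalized to uppercase RNA over {A, C, G, U}; T maps to U and
whitespace is stripped. Characters outside the alphabet (IUPAC ambiguity
codes) are a hard error by default; a permissive mode drops them with a
warning, after which counts refer to the effective (retained) length. All
coordinates are 0-based half-open on the plus strand; reverse-complement
search is deliberately absent because the intended inputs are
positive-strand RNA genomes.

The polyprotein ORF is located as the longest AUG-initiated open reading
frame terminated by an in-frame stop, ties broken toward the earliest start;
the flanking remainders are the 5'UTR and 3'UTR. The stop codon belongs to
the ORF interval but is excluded from amino-acid length and from all
codon-usage statistics: an ORF of 3n nt comprises n − 1 sense codons
(including the start methionine) plus the terminal stop. Curated
annotations can be supplied as a 3-line TSV and override detection.

## Composition statistics

Nucleotide profiles are exact counts with derived fractions, purine and
pyrimidine totals and the Pu/Py ratio (A+G)/(U+C); an empty multiset yields
a defined profile with an undefined ratio rather than an error. Profiles add
component-wise, which gives the conservation identities used throughout:
region profiles sum to the whole-genome profile, and ss + ds compartment
profiles sum to the whole-genome profile, per nucleotide and exactly.

Dinucleotides are counted in overlapping windows of width 2 with no
wraparound (total = length − 1), over the full genome rather than per
region. Suppression is reported as the plain count ratio between a
dinucleotide and its mirror (GpC/CpG, ApU/UpA). The more common
observed/expected odds ratio f(XY)/(f(X)·f(Y)) is exposed as
`dinucleotide_odds_ratio` but is not used in the table-style reports, whose
published counterparts use plain ratios. Report tables round percentages to
1 dp and ratios to 2 dp; JSON output keeps full precision.

## Skew tracks

For an ordered base pair (N1, N2) the window skew is
(N1 − N2)/(N1 + N2); windows where both counts are zero are flagged
undefined and contribute zero to the cumulative track (unreachable in
practice for windows ≥ 100 nt). The cumulative diagram is the running sum of
per-window skews over overlapping windows — the Grigoriev-style convention
in which a constant compositional bias appears as a straight line.

Window geometry: window = round(0.01 × length), step = round(0.2 × window),
both rounded half-away-from-zero and clamped to ≥ 1; windows that would
overhang the 3' end are dropped. This yields 486 windows for a 10794-nt
genome and ~496 for most lengths ≥ 2 kb. For lengths where the step rounds
coarsely relative to 20 % of the window (e.g. 1234 nt: window 12, step 2)
the count can drift well above 500; the "about 500 points" property is a
property of the scheme at scale, not a guarantee per length. The six
reported orientations are GA, CA, UA, CG, UG, UC (first-named minus
second-named), covering all unordered pairs; tracks are antisymmetric under
orientation reversal. Compartment-level skew runs the same fractional scheme
on the concatenated ss (or ds) subsequence in genomic order.

## ss/ds partitioning

The input is an ss-count profile: for each position, the number of
structures in a folding ensemble (≤ 50 in the intended workflow) in which
the position is unpaired. The discrimination rule is inclusive: a position
is single-stranded iff ss-count ≥ n_structures / 2, as a real-valued
comparison with no rounding. Genomes folded as two fragments (the usual
workaround for submission limits near 9 kb) are merged by arithmetically
averaging the ss-counts in the declared overlap (default 1000 nt) *before*
thresholding, so an averaged 24.5 against 50 structures classifies ds.
n_structures is per-dataset, not a constant; a headerless two-column
ss-count file therefore requires it explicitly. Dot-bracket and CT inputs
are treated as degenerate ensembles of one structure.

## Codon usage

The standard genetic code is used; Ile is the single 3-fold family, Met and
Trp are excluded from ENC and (optionally) GC3, and stops are excluded
everywhere. Family homozygosity is F = (n·Σp̂ᵢ² − 1)/(n − 1) with n the
family total; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ where each F̄ₖ averages
over the families of degeneracy k that are computable (n ≥ 2 and F > 0).
An empty 3-fold class falls back to the mean of the 2- and 4-fold class
averages; an empty 2-, 4- or 6-fold class is an error, which cannot occur
for realistic ORFs of a few hundred codons. ENC is capped at 61 in reports
(the uncapped value is available), and a warning is issued below ~60 codons
where the estimator is unstable.

**GC3 definition.** Two conventions exist: G+C at third positions of all
sense codons, or of synonymously variable codons only (excluding Met and
Trp). For the bundled published codon table they give 0.54 and 0.51
respectively. The package defaults to the all-sense-codon definition: it is
the one consistent with the published ENCobs/ENCexp floor of 0.88 for this
genome (0.881 versus 0.876 under the synonymous-only variant), suggesting it
matches the convention of the original analysis software. The
`synonymous_only=True` option restores Wright's stricter convention.

The expected ENC under random codon usage at GC3 = s is
ENCexp(s) = 2 + s + 29/(s² + (1 − s)²), defined on 0 < s < 1. The
ENCobs/ENCexp ratio is reported with the qualitative bands: ≥ 0.8 very weak
or virtually absent bias, 0.6–0.8 weak, below that strong.

**Ranking strings and ties.** Within each codon box (codons sharing their
first two positions; 6-fold families split into their 4- and 2-codon
boxes), third-position nucleotides are ordered by descending within-family
proportion; adjacent entries whose 2-dp proportions differ by at most
`tie_delta` (default 0.02) print "=" instead of ">", with exactly equal
counts breaking order by the fixed priority G, A, C, U. This reproduces the
published tie conventions for the clear cases (Phe 0.49/0.51 "=",
Ser-AGY 0.18/0.19 "=", Asp 0.40/0.60 ">") but no proportion-threshold rule
can reproduce every published ranking simultaneously — the published table
ties Phe at an unrounded gap of 0.011 yet separates Ala A/U at 0.0106 — so
borderline boxes (Ala A/U, Leu C/U) may print "=" where a published table
prints ">". `tie_delta` is configurable per call.

## Synthetic data

The generators exist so that every pipeline stage has inputs with known
ground truth. Defaults are fixed at flavivirus-like study conditions:
length 10794; mononucleotide fractions A 0.277, U 0.214, C 0.219, G 0.291;
unpaired fraction 4107/10794 ≈ 0.3805 under a 50-structure ensemble; and an
A-at-unpaired odds enrichment calibrated in closed form so the expected
unpaired-compartment A fraction equals the observed 44.7 % for a folded
genome of this composition (enrichment ≈ 3.90). One global seed fans out to
fixed per-generator substreams, so adding a generator never perturbs
another's draws.

- *i.i.d. genomes* draw positions independently from the mononucleotide
  frequencies.
- *Markov genomes* run a first-order chain started from its stationary
  distribution. Dinucleotide suppression is imposed by down-weighting
  targeted transitions and renormalizing; because suppression feeds back
  into the stationary distribution, the suppression factors are solved
  jointly (alternating exact one-dimensional root finds on the implied
  stationary ratios) to hit target GpC/CpG and ApU/UpA values — defaults
  2.17 and 1.86.
- *ORFs* are AUG + n i.i.d. sense codons + stop, so internal stops are
  impossible by construction.
- *Pairing profiles* label each position unpaired with probability p_A or
  p_other (odds ratio = the enrichment, level solved by root finding to hit
  the target unpaired fraction), then draw the ss-count binomially with
  per-structure probability 0.8 (unpaired) or 0.2 (paired), reflecting the
  rare contradictory draws about n/2 so the threshold rule recovers the
  labels exactly. Targets that are arithmetically unreachable (e.g. an
  unpaired fraction above what zero enrichment permits) raise an error
  rather than being clipped.

What the synthetic data does *not* emulate: real folding thermodynamics or
base-pair correlation structure (ss-counts are position-independent given
the base), codon autocorrelation along real ORFs, region-specific
composition (UTRs vs ORF), and sequence motifs. Passing recovery tests
therefore demonstrates the correctness of the estimators under the assumed
sampling models, not the biological fidelity of those models.

## Numerical and testing choices

Statistical checks use 3σ normal/binomial approximations with problem sizes
chosen for stability (genomes of 10⁴–5·10⁴ nt, ORFs of 4–6·10³ codons,
Monte-Carlo replicates of 25–100); ratio comparisons use a delta-method
band. The skew sign checks on purine-rich genomes compare against an
empirical null spread estimated from replicate balanced tracks rather than
an analytic bound, since overlapping windows are strongly correlated.
Reports are byte-deterministic for fixed inputs and parameters (figures
exempt); provenance blocks record input hashes, parameter values and the
package version so every reported number is recomputable.

Known limitations: ENC values can differ from legacy software by small
amounts (< 0.5) through different handling of rare families; the
longest-ORF rule is a proxy for manual curation and can extend an intended
ORF through an upstream in-frame AUG in its 5'UTR; and sequence-level
published values (exact genome counts, UTR lengths, dinucleotide ratios of
the real genome) require fetching the GenBank record — the offline test
surface covers the printed count tables and synthetic analogues instead.
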