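# Methods

## Scoring model

Operators are modeled by a position weight matrix over A/C/G/T with the
log-count weight convention

    w(b,k) = ln(N(b,k) + p) − (1/4) Σ_b′ ln(N(b′,k) + p),   p = 0.5,

which forces every column to sum to zero; a sequence's score is the sum of
its positional weights, and thresholds are meaningful only on this scale
(a fixed cutoff of 4.3 is the published convention for NagR scans on it).
Palindromic motifs are handled by count symmetrization — each training
site's reverse complement is added before weights are computed — which
makes the matrix exactly self-reverse-complementary, so
`score(s) = score(revcomp(s))` for every sequence.  Windows containing N
score −∞ and can never be hits.  Information content per column is
`2 + Σ f log2 f` bits from the raw count frequencies, without pseudocount
or small-sample correction: logo parity with any particular renderer is
not a goal, and the simpler estimator is transparent.

Four threshold rules are provided: `fixed` (a value on the score scale),
`min_training_site` (the loosest cutoff recovering every known site),
`percentile` of training-site scores, and `relative_max` (a fraction of
the maximum attainable score — the scale-free convention common in PWM
scanning).  The rules exist because published score cutoffs are only
portable together with the exact matrix and scale that produced them.

## Coordinates and scanning

Internal coordinates are 0-based half-open on the forward strand.
Gene-relative coordinates follow the biologist convention: +1 is the first
base of the start codon, −1 abuts it, there is no 0.  The scan window
defaults to −500..+50 (550 bp), is truncated only at replicon edges
(overlap with a neighboring CDS does not truncate — the window is fixed),
and replicons are treated as linear; windows are never wrapped across a
circular origin.

Every in-window position is scored on the coding strand and its reverse
complement.  A hit must lie entirely inside the window; its gene-relative
position is that of its 5′-most base on the coding strand.  For palindromic
matrices a genuine site produces a mirror hit on the opposite strand at
(nearly) the same position; opposite-strand hits whose starts differ by at
most 2 bp are collapsed to the higher-scoring one, with scores compared at
1e-6 resolution and ties broken toward the '+' strand then the lower start
so the outcome is independent of floating-point summation order.
Same-strand tandem hits are never collapsed.  A physical site inside the
shared intergenic region of a divergently transcribed pair is reported once
per flanking gene but counted once in operator tallies.

## Orthology, operons, consistency filtering

Orthologs are bidirectional best hits (BBH) under global protein alignment
(match +1, mismatch −1, gap open −5, extend −1), keeping pairs with
identity ≥ 0.4 (identical residues / alignment columns) and coverage ≥ 0.7
(aligned residues / longer protein).  Best hits are located with score-only
dynamic programming; full alignments are computed only for mutual best
pairs.

Operons are maximal runs of same-strand, same-replicon genes with
intergenic gaps ≤ 150 bp; the lead gene is the 5′-most (highest coordinate
for − strand operons).  No terminator or promoter model is used — the gap
rule is the standard distance heuristic.

The consistency filter works at the transcription-unit (TU) level: a site
upstream of a TU in genome g is retained iff in ≥ `min_support` (default 2)
other genomes an ortholog of *any* gene of that TU belongs to a TU that
itself carries an above-threshold hit.  Counting support through any
operon member keeps gene fission/fusion across genomes from breaking
support.  All sites upstream of one TU share one fate.  Raising
`min_support` can only remove sites (monotonicity), and on mutually
supporting site families the filter is idempotent.

Footprint reports are ungapped stacks anchored at each genome's
promoter-proximal operator start, with per-column modal-base conservation
— an operator-anchored comparison rather than a full multiple alignment,
which keeps the report independent of MSA parameters.  Per-clade PWM
refinement pools each clade's retained sites (clades from the children of
a user-supplied tree root, or explicit lists) and rebuilds the matrix,
falling back to the global matrix for clades with fewer than two sites.

## Promoter elements and architecture calls

σ70-type promoters are modeled as a −35 hexamer and a −10 hexamer with a
15–19 bp spacer, each scored by a non-palindromic hexamer PWM on the coding
strand, both elements fully upstream of the start codon.  The bundled
training lists (canonical TTGACA / TATAAT families, 12 hexamers each) are a
synthetic stand-in for organism-specific compilations; callers can supply
their own.  The default combined-score cutoff is the weakest training −35
score plus the weakest training −10 score.  In pipeline mode only the
single best promoter call per region feeds the overlap classification.
An operator whose interval intersects either hexamer (in the shared
gene-relative frame) is classified repression-consistent.

## Quantification

EMSA titrations are fit by least squares to the four-parameter logistic
`y = c + (d−c)/(1+(x/e)^b)` with the lower asymptote fixed at 0 and the
upper at 1; `e` is the EC50 in the units of x (nM for protein titrations,
mM for effector titrations) and the sign of `b` encodes orientation
(negative for responses rising with concentration).  The fit is performed
on a geometric-mean-normalized concentration axis in `(b, ln e)`, which
makes it scale-equivariant — multiplying all concentrations by k multiplies
the fitted EC50 by k — and well conditioned; initialization takes `e` at
the response nearest 0.5 and `|b| = 1`, with a small restart grid before
declaring non-convergence.  The 95% CI on `e` comes from the linearized
covariance of `(b, ln e)` with a t quantile at n−2 degrees of freedom
(delta method on the log scale); profile likelihood would be more exact in
small samples but the point estimate is what downstream analysis consumes.
All-zero or all-one response vectors are rejected as degenerate.

Growth curves are integrated by the trapezoid rule over the raw OD
readings (OD·h), with no baseline subtraction or smoothing.  The
affinity–expression association is the Pearson correlation between probe
EC50s and cognate-gene expression fold changes, on the raw values by
default (log flags available, since published figures do not always state
the scale), with a two-sided t-test p-value.

## Synthetic data: what it emulates and what it does not

`simulate_clade` builds one ancestral genome — random sequence at 60% GC,
genes of 300–1500 bp (start codon, non-stop codons, stop) laid out on
alternating strands with 50–400 bp intergenic gaps — and derives each of 5
leaves by i.i.d. substitutions at 5% per site, uniform over the three
alternative bases.  Operators are 21-bp palindromes sampled from a
generating frequency matrix (two 9-bp half-sites at 0.98 per-position
consensus frequency around a 3-bp uniform spacer; ~1.8 bits per informative
column) and planted at uniform −120..−30 relative to 20 regulon genes in
the ancestor; inside planted sites the per-leaf substitution rate is 0.02,
modeling the purifying selection that makes consistency filtering
informative.  Sampled sites are conditioned to at most one informative-
position mismatch, reflecting that functional operators must retain
binding.  Ten decoys, drawn from the same matrix (hence score-
indistinguishable from real operators), are planted post-divergence into
one genome each, upstream of non-regulon genes.

The regulon is designated as whole divergently transcribed pairs (10 pairs
= 20 genes): with alternating strands each pair shares its upstream
intergenic region, so a planted site sits in both members' windows exactly
like a shared operator of a divergent promoter pair, and the set of genes
geometrically downstream of planted sites equals the designated regulon.
Intergenic gaps that must hold two sites (both pair members planted) are
drawn from 200–400 bp.  A training alignment of 20 sites sampled from the
generating matrix is emitted alongside — the synthetic analogue of a
curated known-site collection.

For the synthetic workflow the scan threshold is set by the `relative_max`
rule at 0.65 of the maximum attainable score.  This value was calibrated
on the synthetic score distributions: planted sites (ancestral sampling
plus in-site divergence) score ≥ ~70% of the consensus score, while the
largest background windows across a 5-genome clade sit near ~60%, so 0.65
splits the two populations; it is an analysis-side default, and real-genome
workflows should use a cutoff calibrated to their own matrix (e.g. the
fixed 4.3 convention).

Deliberately not modeled: indels and rearrangements, gene gain/loss beyond
decoy placement, transition/transversion bias, codon-aware protein
evolution, promoter elements in the clade simulator (background GC-rich
sequence contains no credible −35/−10 pairs, so pipeline promoter reports
on simulated clades are empty; promoter calling is validated on dedicated
planted-promoter regions), and realistic inter-genome divergence levels
(real intergenic regions diverge far more than 5%, which makes the
simulated consistency check easier than the real one in one way — decoys
are trivially unsupported — and harder in another — background hits are
conserved across leaves and can only be rejected by the score threshold).
Passing the planted-regulon recovery test therefore demonstrates the
correctness of the machinery, not field performance on real clades.

Titration curves are sampled on a log-spaced grid spanning e/30..30e (8
points) with additive Gaussian noise (σ = 0.03 in the recovery suite)
clipped to [0, 1]; growth curves are logistic with a lag (default K = 1.0
OD, r = 0.8 h⁻¹, lag = 2 h, 25 points over 24 h) floored at 0.  Both are
fully seed-reproducible.

## Problem sizes and numerical choices

The acceptance computations use the default study conditions: 5 genomes ×
50 genes (~59 kb each), 20-gene regulon, 10 decoys, 100 Monte-Carlo
titrations, 40 planted promoter regions.  BBH orthology over all genome
pairs dominates the runtime (~13 s single-threaded).  Scanner-oracle
equivalence is checked on twenty ~4 kb genomes against a per-window
lookup-and-sum enumeration.  Score ties anywhere in the pipeline are
broken by fixed deterministic keys (strand, then coordinate), and all
reports are written without timestamps, so identical inputs and seeds
produce byte-identical output trees.

## Known limitations

* BBH with global alignment assumes roughly one-to-one gene correspondence;
  paralog-rich or highly rearranged clades need a dedicated orthology tool.
* The operon gap rule ignores terminators and condition-specific
  transcription units.
* The 4PL CI is a linearization; for 4-point curves it can be optimistic.
* Promoter calling reports the best-scoring element pair, not an ensemble;
  genes with multiple promoters are represented by one call.
* The consistency filter assumes the scanned genomes are annotated with
  comparable gene models; systematic annotation differences (missed genes)
  erode support counts.
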