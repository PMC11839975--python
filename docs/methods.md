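# Methods

## Expression normalization

Raw counts are converted per sample to the fraction of transcripts τ:
with gene lengths available (the default), each count is first divided by
its gene's length so the fraction estimates relative transcript molarity
(TPM on a 0–1 scale); a flag switches to plain count fractions when lengths
are unavailable. Replicates are collapsed to one column per stage by the
per-gene median (the median of an even number of replicates is the mean of
the two central order statistics). Because a column of per-gene medians no
longer sums to one, each stage column is renormalized to unit sum
afterwards; all weighted indices are invariant to per-stage positive
rescaling, so this affects presentation only.

Standardized profiles are built in three steps. (1) Genes with more than
two zero-expression stages are discarded. (2) Remaining zeros are filled:
an interior zero takes the mean of the two adjacent stage values, a zero in
the first or last stage copies its single neighbor; adjacent zeros are
resolved by repeated left-to-right passes until stable, and a profile that
still contains a zero afterwards (both neighbors zero) is reported as
degenerate by gene id. (3) Each profile is log2-transformed and centered on
its own median. The centering is done on the log scale so that the row
median is exactly zero also for even stage counts (on the linear scale the
two operations do not commute with an even-count median). An audit
classifies every input gene exactly once: `discarded`, `interpolated` (any
interior fill), `edge_filled` (boundary fills only), with
`retained = interpolated + edge_filled + untouched`.

## Phylostratigraphy

A gene's phylostratum is the smallest (oldest) lineage internode among the
taxa it hits at e ≤ cutoff; the comparison is inclusive and the default
cutoff is 10⁻³. Genes without a qualifying hit are reported as unassigned
and excluded from all downstream indices rather than defaulted to the focal
stratum. Hits to taxa missing from the lineage map raise an error — silent
dropping would bias ages young. The robustness sweep recomputes the map at
the standard 11 cutoffs (10 … 10⁻⁴⁰) and reports any gene whose assignment
becomes *older* under a stricter cutoff; this is impossible under the
oldest-hit rule, so a non-empty report indicates corrupt input. Lineage
maps can be derived from a Newick consensus phylogeny: each taxon is
assigned the 1-based index of its divergence node on the root→focal path.

## Weighted indices

TAI, TdNI, TdSI and TCBI are the same expression-weighted mean with
different weights (phylostratum, dN, dS, ENC). Each index uses the
intersection of expressed genes and genes carrying that weight, so gene
universes differ per index and are reported as `n_genes_used`.
Zero-expression genes contribute zero weight, which is numerically
identical to excluding them from that stage's sums. Cumulative TAI
restricts the gene set to phylostrata 1..k; min–max normalization maps a
profile onto [0, 1] and refuses constant profiles. Per-phylostratum
relative expression min–max scales the stratum's mean expression across
stages and refuses strata whose mean profile is constant.

## Effective number of codons

Wright's Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, with per-family codon
homozygosity F = (nΣp² − 1)/(n − 1). Conventions: Leu/Ser/Arg form the
six-fold class; Met/Trp contribute the constant 2; families with n ≤ 1 or
F ≤ 0 are excluded from their class average; a degeneracy class with no
computable family borrows the mean of the computable class averages; the
estimate is capped at 61, since on short sequences the estimator can exceed
the theoretical maximum. Internal stop codons and non-ACGT codons are
errors by default (configurable to skip); a terminal stop is allowed.

## Flat-line test

The statistic is the variance of the index profile across stages. The null
permutes gene weights while keeping the expression matrix fixed, so
stage-wise expression structure is preserved and only the gene-to-weight
association is broken. Default p is the empirical
(1 + #{null ≥ observed})/(1 + n_perm), requiring at least 100 permutations;
a gamma distribution fitted to the null variances (location fixed at 0) is
available as a smooth-null option. The per-stage mean ± sd of permuted
profiles is returned as the null band. Seeds are mandatory wherever
permutations are drawn.

## Enrichment

Upregulated genes at a stage are those with standardized value ≥ 0.5
(inclusive), i.e. at least 0.5 log2 units above their own profile median.
The two-sided hypergeometric p sums the probabilities of all outcomes at
most as likely as the observed one (minimum-likelihood convention, with a
1 + 10⁻⁷ relative slack absorbing floating-point ties; doubling the smaller
tail is available as an option). Effect direction is the log2 ratio of the
stage frequency k/n to the background frequency K/N; when k = 0 the ratio
is stabilized with Haldane–Anscombe 0.5 pseudo-counts,
log2(((k+0.5)/(n+0.5))/((K+0.5)/(N+0.5))). The background defaults to genes
with at least one annotation, the standard enrichment universe, and is
configurable to the whole genome. Benjamini–Hochberg adjustment is applied
per stage by default (matching per-stage reporting), with a global family
across all (stage, term) tests as an option. Annotations are tested as
supplied; no GO-graph propagation is performed.

## Effect sizes

`hedges_g` reports g = J·(mean(b) − mean(a))/s_pooled with
J = 1 − 3/(4(n₁+n₂−2) − 1), alongside the pooled-variance two-sided
Student t-test and the 95% confidence interval of the raw mean difference
on n₁+n₂−2 degrees of freedom.

## Synthetic data

The generator emulates a 12-stage somatic-embryogenesis series (EI…JP,
heart stage H as the phylotypic stage) in 3 replicates, with genes over 18
phylostrata. Per-gene log2 baselines are Normal(5, 1.5); the hourglass is a
single age-weighted Gaussian bump (sd 1.5 stages) over the stage index:
old genes (low phylostratum) gain up to `effect_size` log2 units at the
phylotypic stage, young genes the complement at the extremes, and
`effect_size = 0` makes stage means exchangeable. Counts are negative
binomial with common dispersion (default size 5, variance = μ + μ²/5;
dispersion → ∞ gives Poisson) and log-normal library sizes (sd 0.2 on the
log scale). Phylostrata are drawn with geometrically decaying weights
(ratio 0.85) so most genes are ancient, as in real phylostratigraphic maps,
with every stratum forced non-empty. dN and dS are gamma(shape 2) with
scale increasing linearly in phylostratum, so younger genes are more
diverged and the divergence indices co-move with TAI; the ENC target rises
from ~30 (old, biased) to ~57 (young, near-uniform).

Hit tables list one hit per taxon for every stratum from the gene's true
phylostratum to the focal species, with e-values log-uniform below 10⁻⁴, so
assignment at the default cutoff recovers the truth exactly at noise 0;
with probability `noise` a gene gains a spurious stratum-1 hit, the
worst-case false signal. Coding sequences draw amino acids uniformly over
the 18 degenerate families and solve the per-gene preferred-codon bias
against the finite-length ENC estimator itself (largest-remainder rounding
of within-family codon counts removes multinomial noise), keeping realized
ENC within about ±2 of target for ≥300-codon sequences. GO labels are
sparse (Poisson(2) terms per gene from a 1/rank term-frequency law).

What the generator does not emulate: read-level sequencing artifacts,
mapping biases, gene–gene correlation structure, batch effects, and
annotation hierarchies. Passing tests therefore demonstrate correctness and
calibration of the statistics under a realistic noise model, not robustness
to every property of real libraries.

## Problem sizes and numerical choices

The test suite exercises the statistical properties at sizes chosen to make
sampling error negligible relative to the tested tolerances: flat-line
calibration uses 500 null simulations of 200 genes × 12 stages × 3
replicates with 1000 permutations (rejection rate at α = 0.05 expected in
[0.03, 0.08]); hourglass recovery uses 100 simulations of 2000 genes at
effect size 2.0; index–oracle equivalence uses 100 random 50×12 instances
at 10⁻¹² relative tolerance; the exact hypergeometric test is verified
against rational-arithmetic enumeration over every count combination with
N ≤ 60. The acceptance script reruns the same analyses at 30 recovery and
100 null simulations. Ties in reciprocal-best-hit selection break by
highest bitscore, then lowest e-value, then lexicographic subject id, so
results are independent of hit order.

## Known limitations

The per-stage renormalization after replicate collapse means absolute τ
values are not comparable across packages that skip it (indices are).
ENC on very short sequences is dominated by estimator bias; values are
capped but not bias-corrected. The flat-line test's gamma option assumes
the null variance distribution is well-approximated by a gamma with zero
location, which can be poor with very few stages. Genome-scale gene
universes (≈3×10⁴ genes, multi-hundred-proteome homology databases) are
supported by the data structures but not shipped; all bundled analyses run
on synthetic data.
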