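# Methods

## The measurement model

Bisulfite treatment converts unmethylated cytosines to uracil (read as T);
methylated cytosines are protected. A per-cytosine report therefore gives, at
each cytosine on each strand, a count of methylation-supporting reads `m` and
converted reads `u`. Conversion is imperfect: a truly unmethylated cytosine
still reads as methylated with probability ε (the non-conversion rate). The
package estimates ε from a spike-in contig known to be fully unmethylated:

    efficiency = Σu / Σ(m + u)  over all spike-in cytosines,  ε = 1 − efficiency.

All contexts of the spike-in are pooled by default (the control is
unmethylated in every context); a CpG-only estimate is available via the
records filter. The estimator is the binomial MLE, so its standard error is
√(ε(1−ε)/N) with N the total spike read count — with a ~1% spike at ≥10×
depth, ε is known to a few parts in 10⁵ and calibration error is negligible
relative to the quantities it corrects.

### Genome-wide level

Per context, the level is `max(0, 100·Σm/Σ(m+u) − 100·ε)` over all non-spike
cytosines of that context. Subtracting ε (the *non*-conversion rate) is the
only reading under which the correction is small and the result non-negative
for sparse methylomes; the clamp handles sampling fluctuations below ε. A
context with zero coverage is reported as missing, never as 0.

### Per-CpG calls

Only CpG-context sites with coverage n ≥ `min_cov` (default 10) are tested.
The null is that all apparent methylation is non-conversion:
p = P(Binomial(n, ε) ≥ m), computed as the exact upper tail
(`scipy.stats.binom.sf`, verified against exact rational summation to
< 1e−12 for n ≤ 200). The test orientation uses the methylated count as the
success with success probability ε; this is the one-sided test equivalent to
testing a deficit of converted reads at success probability 1 − ε, and is the
only orientation that yields small p-values at methylated sites. BH correction
is applied once over all tested sites genome-wide; a site is called methylated
at q ≤ α (default 0.05, inclusive). ε = 0 is handled as the degenerate null
(p = 0 if m > 0 else 1). Calls are strand-specific; symmetric-CpG destranding
is deliberately not performed.

### Weighted methylation

For a region R with CpG records {(mᵢ, uᵢ)}: `W(R) = Σmᵢ / Σ(mᵢ + uᵢ)`.
Uncovered CpGs contribute 0/0 (counted in `n_cpg` but not zero-inflating);
W is undefined (missing) at zero total coverage. Numerator and denominator are
additive, so pooling sub-regions is exact — the invariant the tests check.
Gene-body levels span the full gene extent (exons + introns); an exon-only
variant is a row filter away since every exon instance is emitted. Gene
classes: unmethylated (W = 0), background (0 < W ≤ ε, indistinguishable from
non-conversion), methylated (W > ε), highly methylated (W > 0.7).

### Feature classification

Precedence exon > intron > TE > intergenic, so every base has exactly one
category. Exon rank is transcription order (rank 1 is the 5′-most exon of the
chosen transcript). Intergenic space is split into fixed windows (default
2 kb) so the background enters rank tests as many observations; the pooled
background level is the count-sum over windows. The exon-rank comparison uses
ranks 1–6 (instances of rank ≥ 7 are recorded but excluded from that test),
giving the seven-group Kruskal–Wallis (df = 6) against intergenic background.

## Codon degeneracy

Coordinates are 0-based half-open internally; GFF3 enters as 1-based
inclusive, BED as 0-based half-open. One transcript per gene is used (longest
total CDS, ties by transcript ID). The CDS is concatenated in genomic order
and reverse-complemented whole for minus-strand genes. A coding position at
codon offset o is d-fold degenerate when d of the four bases at o encode the
same amino acid under the standard code; substitutions creating a stop count
as amino-acid-changing, and stop-codon positions themselves are excluded.
Positions claimed by overlapping genes with conflicting degeneracy are dropped
(and counted); agreeing claims are kept once. Codons containing N are skipped
site-wise rather than invalidating the gene.

## Housekeeping genes and the gene-level comparison

A putative housekeeping gene is expressed in every sample of every supplied
dataset — strictly positive by default (`min_expr = 0`), or ≥ `min_expr` when
a threshold is given; genes absent from any matrix are excluded, and missing
values count as not expressed. The comparison set ("other") is every
non-housekeeping gene with a defined methylation level and any detected
expression. The two groups are compared by Welch's t on gene-body weighted
levels (the unequal-variance form; group sizes and variances differ
materially).

## The degeneracy model

The response is per-site methylation status from the caller (not raw
fractions). The model is a binomial-family GLM (logit link) of status on
degeneracy (categorical, reference 0-fold), housekeeping (reference false) and
their interaction, fitted by IRLS (tolerance 1e−8, max 100 iterations;
non-convergence raises). Because both covariates are categorical the data are
aggregated to (degeneracy × housekeeping) cells before fitting — identical
likelihood, far cheaper. Term tests are Type-II likelihood-ratio chi-squares:
each main effect is dropped from the additive model, the interaction is the
full-vs-additive comparison; df equals the number of dropped coefficients
(3 for degeneracy across four classes, 3 for the interaction, 1 for
housekeeping). Quasi-complete separation (e.g. a fully unmethylated stratum)
is flagged on the fit object, never silently reported; empty levels are
dropped with a warning and the df adjusted.

Pairwise contrasts between degeneracy levels are Wald z statistics on effect
differences, signed as (lower fold − higher fold) so a positive z means the
more constrained class is more methylated. The single-step ("Tukey-style")
adjustment is the max-|z| multiplicity correction estimated by seeded
Monte-Carlo (20,000 draws by default) from the contrasts' joint normal, with
the raw p as a floor; Bonferroni is available as the conservative alternative.
Contrasts can be evaluated at either housekeeping stratum
(`at_housekeeping=True` adds the interaction coefficients).

## Rank tests

Kruskal–Wallis uses the tie-corrected H with df = k − 1; the all-values-
identical case is defined explicitly as H = 0, p = 1. Dunn post hoc z uses
pooled mean ranks with the standard tie correction and BH-adjusted p-values
(no established Python implementation of Dunn's test is available here, so it
is implemented from the standard formula and checked against the no-tie
closed form).

## The synthetic-data generator

Defaults are the package's study conditions, chosen once: 2 × 300 kb
chromosomes at 40% GC, a 10 kb unmethylated spike-in, 150 non-overlapping
genes (4–8 exons, CDS 300–1500 bp, valid ORFs; exon intervals equal CDS
intervals — no UTRs, as nothing downstream consumes them), TE fraction 0.15,
mean depth 30, ε = 0.01, class methylation probabilities 0.7 (housekeeping
bodies), 0.2 (other bodies), 0.05 (intergenic), 0.01 (TE), housekeeping
fraction 0.35, two expression datasets × 4 samples with per-sample dropout
probability 0.3 for non-housekeeping genes. These sizes give every feature
class ≥ 5,000 CpGs so class-level recovery is measurable to well under 0.02,
while the whole pipeline runs in seconds.

Observation model per cytosine: coverage n ~ Poisson(depth) i.i.d., methylated
count k ~ Binomial(n, π + (1 − π)ε) — a single-error model in which
methylated reads never under-report; over-conversion of methyl-cytosines is
ignored, consistent with calibrating on a single conversion rate. π is a
per-site Bernoulli read probability, not a mixture of on/off epialleles, and
neighbouring CpGs are independent. Optional logit shifts at 0-fold and 2-fold
degenerate CpGs inject the degeneracy–methylation association; site-level
observations for the regression calibrations are generated directly by
`simulate_site_observations` with a realistic coding-site degeneracy mix
(0-fold 55%, 2-fold 20%, 3-fold 5%, 4-fold 20%).

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: read-level artifacts (M-bias, mapping error,
duplication), spatially correlated methylation along chromosomes, biological
replicate variance, beta-binomial overdispersion of per-site counts, UTRs and
alternative isoforms, and genome-scale CpG depletion by deamination. Tests on
this generator validate the estimators and their calibration under the stated
model, not robustness to those artifacts.

## Numerical and degenerate-input choices

* Exact binomial tails via the regularized incomplete beta; tested against
  rational-arithmetic summation.
* BH applied once per calling run over exactly the tested set; q ≤ α
  inclusive.
* Weighted levels undefined (not 0) at zero coverage throughout, and carried
  as missing through every summary.
* Softmasked genome bases are uppercased and treated as normal; characters
  outside {A,C,G,T,N} are load errors naming the record.
* Empty cytosine reports load as empty collections with a warning; malformed
  rows (negative counts, bad strand/context) are errors with the line number.
* Monte-Carlo pieces (single-step adjustment, generator) are fully seeded;
  identical seeds give byte-identical outputs.

## Problem sizes

The default test and acceptance runs use the generator defaults above
(~258,000 cytosine records, ~55,000 tested CpGs), 10,000 null CpGs for FDR
calibration, 20 replicates of 50,000 sites for effect detection and 200
replicates of 20,000 sites for null calibration of the LR test — sizes at
which every Monte-Carlo band used in the tests is decisive.
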