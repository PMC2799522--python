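# Methods

## Study design and model

`robustqtl` targets panels of inbred or recombinant inbred lines: each
strain carries one fixed, homozygous genotype and is phenotyped in
replicate individuals, optionally stratified by sex and environmental
condition. Continuous traits (typically log2 expression) are modeled per
strain as replicate draws around a strain-specific center, so that

* **within-strain** spread reflects micro-environmental (and stochastic)
  variation among genetically identical individuals, and
* **between-strain** spread of strain medians reflects the effect of
  genetic background, with the median over ~10–20 replicates suppressing
  most micro-environmental noise.

A robustness QTL is a marker whose genotype associates with one of these
dispersions but **not** with the trait's central value. The two
signatures are mapped separately:

**GR scan.** For each eligible trait/marker pair, strain medians are
grouped by genotype class and tested with the median-variant
Fligner–Killeen (FK) statistic: deviations |xᵢⱼ − medianᵢ| are pooled,
ranked (midranks on ties), transformed through half-normal scores
a(r) = Φ⁻¹(½ + r/(2(N+1))), and

    d = Σᵢ nᵢ (Āᵢ − ā)² / V²,

where V² is the (N−1)-denominator variance of all scores; d is referred
to χ²(k−1). The test is rank-based, hence distribution-free,
outlier-robust, location-invariant and scale-invariant — all properties
the test suite asserts. When a group has odd size, one deviation is
structurally zero, which biases slightly against calling the odd-sized
group high-dispersion; the package exposes a diagnostic probe for this
(`fk_odd_bias_probe`) but makes no correction, since permutation carries
the same bias into the null.

**ER scan.** Per-strain dispersions (SD with the n−1 denominator by
default; coefficient of variation optionally, with a configurable mean
floor of 1e−8 against division blow-up) are Pearson-correlated with the
0/1 genotype — equivalent to a two-sample t-test in this balanced
setting. A hit requires the genotype to explain at least half the
variance in within-strain variability (r² ≥ 0.5; at 19 strains this is a
two-sided nominal p ≈ 7.1×10⁻⁴).

**Macro-ER scan.** With c ≥ 2 labeled conditions, each strain's
dispersion input becomes the SD over its c per-condition medians (so
each rests on only c points); the ER machinery then applies unchanged.

## Filters, in order

1. **Trait variability floor** (`sigma_min`, default 0.15): GR mode
   requires between-strain SD of strain medians above the floor, ER mode
   the median within-strain SD. Traits flat everywhere cannot show
   dispersion differences anywhere.
2. **Marker balance** (`min_minor_strains`, default ⌊n/2⌋, i.e. 9 of
   19): maximally balanced markers give the two-group tests their best
   power. Heterozygous or missing calls remove a strain from that marker
   only; markers missing in more than half the strains are dropped at QC.
3. **Median-QTL exclusion** (`median_qtl_alpha`, default 0.01): the pair
   is discarded if strain medians correlate with genotype at nominal
   p < 0.01 (Pearson, df = n−2). Not correcting this for multiple tests
   is deliberately conservative — it excludes *more* pairs with any hint
   of a mean effect.
4. **Replicate floor** (`min_replicates`, default 3): the smallest count
   for which an SD is meaningful; strains below it get no dispersion.
5. **GR listing threshold** (`gr_alpha`, default 1e−3): nominal χ² level
   at which a GR pair enters the hit table. The most extreme statistic a
   9/10 strain split can produce is d = 12.05 (nominal p ≈ 5.2×10⁻⁴), so
   maximal-separation hits always list. Genome-wide inference never
   rests on these nominal values: significance and FDR come from
   permutation.

Markers with identical genotype columns are collapsed to one
representative when hits are *counted* (`count_nonredundant_hits`),
though all are listed.

## Permutation inference

Significance of a scan's hit count is assessed by re-pairing strain
genotypes with strain phenotypes through a random bijection, which
preserves every trait–trait and marker–marker correlation. The add-one
estimator p = (b+1)/(B+1) avoids zero p-values; FDR = min(1,
mean(permuted)/observed). When two strata share a strain panel (males
and females), the same bijection must be applied to both within each
permutation — separate permutations would understate the chance overlap
between strata, because the strata share genotypes. Defaults: B = 1,000
for FDR, 10,000 for headline empirical p.

Power is estimated by strain-balanced split halves: scan both halves,
estimate each half's FDR and the false-positive overlap frequency from
genotype randomizations, and take power = (observed overlaps − expected
false-positive overlaps) / estimated true positives. The expected
overlap between two hit lists is n·(tp·power + fp·fp_overlap), and the
chance of zero overlaps given expectation λ is e^{−λ}.

## Cis/trans annotation

A hit is cis when marker and gene share a chromosome and lie within an
inclusive window (default 5 Mb = 5,000,000 bp exactly); a trait is
cis-classified if *any* of its hit markers is cis. Gene position is a
single representative coordinate — the feature map's point — chosen for
determinism over a gene-body interval. The fraction of true-positive
hits acting in cis is (cis hits − expected chance cis) / (total hits −
expected false positives), clamped at zero and undefined when the
denominator is non-positive; the chance cis count comes either from
permutation-derived hit lists or from uniform random marker assignment
(both estimators are provided, since either is defensible).

## Two-strain replication

An ER QTL whose genotype differs between two strains predicts the more
variable strain per gene. Because one strain may be globally noisier,
each predicted gene's log2 variance ratio is baseline-corrected by the
mean ratio over non-predicted genes before calling agreement; global
scaling of one strain's variances then cancels exactly. Per-gene
strength is a one-sided F-test in the predicted direction; the critical
ratio for a two-sided test is the matching F quantile (≈ 5.8 at seven
replicates per strain, α = 0.05). Genes with more than one missing
value in either strain are ineligible. The excess of agreeing genes
over the n·α/2 chance expectation is tested with an exact binomial
tail; a Poisson tail gives a similar magnitude, and the package reports
the binomial.

## Synthetic panels

The generator emulates a single-sex arm of the mouse design: 182
individuals, 19 strains, two genotype classes of 91 individuals each.
Since 182 does not divide evenly by 19, the baseline class holds 9
strains (8×10 + 1×11 individuals, round-robin) and the affected class
10 strains (9×9 + 1×10) — the even affected-class strain count makes
the ±shift sign split exact (5 strains +2, 5 strains −2, assigned in
strain order under the seed). Effect classes:

| class | baseline genotype | affected genotype |
|-------|-------------------|-------------------|
| NULL  | N(0, 1)           | N(0, 1)           |
| ER    | N(0, 1)           | N(0, 1.5)         |
| GR    | N(0, 1)           | N(±2, 1) by strain half |
| ER+GR | N(0, 1)           | N(±2, 1.5)        |

Traits whose strain medians correlate with genotype at p < 0.01 are
discarded and regenerated (a flag disables regeneration), keeping class
sizes exact; for NULL/ER classes the discard fraction sits near the
nominal 1%.

What the generator does **not** emulate: microarray probe effects and
intensity-dependent noise, batch structure, correlated traits, linkage
between markers, or population structure among strains. Passing tests
on these panels therefore demonstrate the statistical machinery, not
freedom from those real-data complications — which is why the package
also ships the confound diagnostics.

**Interference study.** For each of ten thresholds per scan (|r| = 0.20
… 0.65 step 0.05 for ER; χ² = 2 … 11 step 1 for GR) the study forms the
ratio of the detection rate among single-effect traits to that among
ER+GR traits. The acceptance script uses 10⁵ traits per class (about
ten seconds of compute); ratios are reported with delta-method 95%
Monte-Carlo intervals, and a ratio with a zero denominator rate is
reported missing. ER-side ratios sit within Monte-Carlo noise of 1 at
every threshold — a strain-constant mean shift cannot move a
within-strain SD. GR-side ratios are ≤ 1.008 at the nine lower
thresholds; at χ² = 11, which sits within one unit of the maximal
attainable d = 12.05, the extra median noise of the joint effect
(σ = 1.5 vs 1) breaks complete rank separation in ~5% of traits and the
ratio is ≈ 1.05. This last point is a structural property of the rank
test at the grid's extreme, not simulation noise.

**Mean-QTL masquerade.** A hidden causal variant carried by each
affected-class strain independently with probability 0.5 (and absent
from the baseline class) shifts carrier strain means, inflating the
affected class's median dispersion. At matched nominal level (0.01),
the median filter catches these traits at a higher rate than the FK
test would flag them at every shift, and in the full-penetrance limit
(carrier probability 1 — an ordinary mean QTL) the filter excludes
>99% of traits once the shift reaches twice the noise scale. One edge
case is worth recording: with *exactly* half the affected strains as
carriers, the Pearson correlation between strain medians and genotype
saturates at r = 0.567 (p = 0.0113) as the shift grows — just above the
0.01 exclusion bar — while the FK statistic saturates at its maximum;
under the Bernoulli carrier model such knife-edge configurations arise
only a quarter of the time and the aggregate ordering holds.

## Numerical choices and degenerate inputs

* Ties get midranks throughout; rank tests are discontinuous in ties,
  so property tests that perturb inputs use exact (integer/dyadic)
  arithmetic.
* An all-constant FK input, or any input with zero score variance,
  yields a flagged result with p = 1 rather than an exception, so scans
  over degenerate traits proceed.
* A constant dispersion vector in the ER scan skips the pair; constant
  strain medians pass the median filter (no mean signal) with a flag.
* The χ² reference for d is known to be conservative at panel sizes
  like N = 19 (measured null rejection ≈ 0.025 at nominal 0.05, matching
  an independent implementation); permutation inference is unaffected.
* Empirical p uses add-one; bootstrap CIs are percentile, with
  degenerate resamples redrawn (counted and reported); all stochastic
  code takes explicit integer seeds with child streams derived
  deterministically.
* Coordinates are 1-based bp in TSV maps; a BED reader converts 0-based
  half-open starts. "Mb" means exactly 10⁶ bp.

## Known limitations

* Markers are tested marginally — no interval mapping, haplotypes, or
  kinship correction (structure is *diagnosed*, not corrected).
* Nominal FK p-values are conservative at small strain counts; treat
  them as orderings, and use permutation for calibrated significance.
* With only ~19 strains, power analyses show these scans give a
  coarse-grained view; hit lists at permutation significance still
  carry substantial FDR, which the permutation machinery quantifies
  rather than eliminates.
* The anti-bias FK variant for odd group sizes is an extension point
  only; it is not implemented, and no alternative dispersion tests
  (Levene, Brown–Forsythe) ship in this version.
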