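# robustqtl

Genetic mapping of **phenotypic robustness** in inbred strain panels.

Most QTL mapping asks where in the genome a trait's *mean* is controlled.
`robustqtl` instead maps loci that control a trait's *variability* — its
robustness to perturbation — in panels of inbred (or recombinant inbred)
lines where each genetically identical strain is phenotyped in many
replicate individuals:

* **GR (genetic robustness) QTL** — loci where one genotype class shows
  greater *between-strain* dispersion of strain medians, i.e. one allele
  buffers the effect of genetic background variation. Tested with the
  median-variant **Fligner–Killeen** rank statistic: per genotype class
  the strain medians are median-centered, the pooled absolute deviations
  are jointly ranked and transformed through half-normal scores
  a(r) = Φ⁻¹(½ + r/(2(N+1))), and

      d = Σᵢ nᵢ (Āᵢ − ā)² / V²  ~  χ²(k−1)

  with Āᵢ the mean score in class i, ā the grand mean, V² the score
  variance.
* **ER (environmental robustness) QTL** — loci where one genotype class
  shows greater *within-strain* dispersion among replicates (a
  gene–environment interaction). Tested by Pearson correlation of
  per-strain SDs with genotype; a hit requires r² ≥ 0.5.
* **macro-ER QTL** — dispersion of per-condition strain medians across
  defined environmental treatments, through the same machinery.

Every scan first discards trait/marker pairs whose trait *median*
associates with genotype at nominal p < 0.01, so ordinary mean-effect QTL
cannot masquerade as robustness QTL. Genome-wide significance and FDR come
from strain-label permutations that preserve all trait and marker
correlation structure. Supporting modules classify hits as cis/trans
(5 Mb window), replicate ER predictions in independent two-strain panels
(variance-ratio F-tests with baseline correction), run confound
diagnostics, and generate synthetic panels with planted ER/GR/ER+GR
effects.

## Worked example

Simulate a miniature study (19 strains, 182 individuals, planted
effects), scan it, and classify hits:

```sh
robustqtl simulate --seed 23 --out demo/
robustqtl scan --mode gr --pheno demo/phenotype.tsv \
    --geno demo/genotype.tsv --markers demo/markers.tsv --out demo/hits.tsv
robustqtl classify-cis --hits demo/hits.tsv --features demo/features.tsv \
    --markers demo/markers.tsv --out demo/hits_cis.tsv
```

which prints

```
10 hits -> demo/hits.tsv
3 cis traits of 5 -> demo/hits_cis.tsv
```

The GR scan lists every planted GR and ER+GR trait at the causal marker
and at its redundant duplicate (statistic d ≈ 11.8, near the maximum of
12.05 attainable with a 9/10 strain split; nominal p ≈ 6×10⁻⁴). The
fixture places planted GR genes 1 Mb from the causal marker, so those
three come back as cis traits, while the ER and ER+GR genes (placed on
another chromosome) stay trans. The same operations are available as
library functions (`robustqtl.gr_scan`, `er_scan`, `permutation_test`,
…) on pandas-backed panel objects.

Library-level example of the core statistic:

```python
>>> from robustqtl import fk_statistic
>>> res = fk_statistic([[0, 1, -1], [0, 5, -5]])
>>> round(res.d, 3), round(res.nominal_p, 3)
(1.13, 0.288)
```

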