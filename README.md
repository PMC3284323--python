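# ccqtl

QTL mapping and shared-ancestry interval narrowing for eight-founder
recombinant inbred panels (Collaborative-Cross-style populations).

## The problem

Multiparent recombinant inbred panels descend from eight inbred founder
strains — five closely related "classical" strains and three deeply
diverged wild-derived strains — mixed by funnel breeding and then inbred.
A quantitative trait measured across such lines can be mapped by
regressing it on inferred founder-haplotype dosages, but the resulting
confidence intervals still span megabases and hundreds of genes.  `ccqtl`
implements the full analysis chain plus the narrowing step that makes
these panels unusually powerful: if the QTL is biallelic, the founders
carrying the same functional allele should be descended from one
ancestral haplotype somewhere in the interval, so a region where those
founders are nearly identical (and distinct from the other allele group)
pinpoints the candidate — often cutting the interval by an order of
magnitude.

The package is exercised end-to-end on synthetic data: the
`ccqtl.simulate` module generates founder panels on a strain tree,
funnel-bred mosaic genomes with residual heterozygosity (5–14 generations
of sib mating), and phenotypes driven by planted biallelic QTL whose
functional allele is shared identically by descent.

## What it computes

* **Ancestry** (`ccqtl.ancestry`): a 64-state haplotype-pair HMM turns
  line genotypes into founder dosage matrices `d ∈ [0,2]⁸`, `Σₖ dₖ = 2`;
  SNPs between which no line's maximum-a-posteriori ancestry changes are
  collapsed into mapping intervals.
* **Scan** (`ccqtl.scan`): per interval,
  `LOD = (n/2)·log₁₀(RSS₀/RSS₁)` from the least-squares fit of the
  phenotype on the eight dosage columns (additive model); genome-wide
  thresholds by permutation; 1.5-LOD support intervals; allele effects
  scaled as deviations from the dosage-weighted population mean;
  conditional scans with a locus genotype as covariate.
* **Narrow** (`ccqtl.narrow`): founders split at the greatest gap between
  ordered allele effects (intermediate effects flagged ambiguous);
  shared-ancestry regions = maximal SNP runs with all within-group
  pairwise identities ≥ 98% (het/missing sites omitted, boundaries
  anchored on full-group matches), annotated with cross-group identity
  and exclusivity; private-SNP filters; interval-reduction reports and
  candidate-gene overlap.
* **Phylo** (`ccqtl.phylo`): per-region SNP alignments, p-distances,
  neighbor-joining trees, site-bootstrap supports.
* **Strain stats** (`ccqtl.strain_stats`): log transforms for count
  traits, one-way strain ANOVA, heritability as the intraclass
  correlation `r₁ = (MSB−MSW)/(MSB+(n−1)MSW)` and the coefficient of
  genetic determination `g² = (MSB−MSW)/(MSB+(2n−1)MSW)`, variance
  explained by a locus genotype, and a trait ~ expression (ΔCt) +
  genotype linear model.

## Worked example

```bash
ccqtl run --seed 1 --outdir demo/
```

simulates 80 lines on a two-chromosome 120-Mb desk genome with one
planted QTL (high allele shared IBD by C57BL6J, NODShiLtJ, NZOHlLtJ at
chr1:30 Mb, 40% heritability), infers ancestry with the HMM, scans,
narrows and builds the candidate-region tree.  `demo/report.json` from
that exact command contains:

```
peak LOD 14.28 at chr1:28,233,388   (95% permutation threshold 5.27)
1.5-LOD interval 26,599,784–32,853,760  (6.254 Mb)
allele effects: C57BL6J +3.09, NZOHlLtJ +2.64, NODShiLtJ +1.54, ...
grouping: high = {C57BL6J, NODShiLtJ, NZOHlLtJ}
shared-ancestry candidate 29,340,801–30,912,840 (1.572 Mb): 75% reduction
tree: (NODShiLtJ:0,NZOHlLtJ:0,(C57BL6J:0.018,(...)93:0.039)53:0.001);
strain stats: r1 = 0.839, g2 = 0.722, QTL explains 48.8% of line variance
```

Reading this: the scan localizes the planted QTL and its three-founder
high group exactly; the shared-ancestry step shrinks the 6.25-Mb
confidence interval to the 1.57-Mb block that was planted as identical by
descent; the candidate-region tree collapses the three high-group
founders onto a single branch point (zero-length tips) while the
wild-derived founders sit on long branches.

Each stage is also available separately (`ccqtl simulate`, `ancestry`,
`scan`, `narrow`, `phylo`, `stats`) on VCF/TSV/CSV/BED/newick files, and
as plain library calls.

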