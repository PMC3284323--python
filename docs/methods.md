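# Methods

This note documents the models, defaults and engineering decisions behind
`ccqtl`, and what the synthetic validation does and does not demonstrate.

## Synthetic data model

**Founder panel.** Biallelic sites evolve independently down a fixed
eight-tip strain tree under the symmetric two-state model: an allele
flips along a branch of length `t` with probability `(1 − e^{−2t})/2`.
The default tree places the five classical strains on short branches of
one clade and the three wild-derived strains on long branches, giving
classical–classical background identity near 90% and classical–wild
identity near 60%.  The classical branches were chosen at that scale so
that identical-by-descent blocks (identity 100%) are cleanly separable
from background similarity at the 98% threshold, mirroring the real
situation where IBD segments stand out against ~90% genome-wide identity
among classical strains.  Sites are i.i.d.; the generator does not model
linkage-scale haplotype mosaics *within* founders, recombination
hotspots, or structural variants.  Because local founder haplotype
structure is planted explicitly (`plant_ibd_block` copies one founder's
alleles across a region to a founder set), synthetic tests show the
narrowing machinery works where shared ancestry exists; they say nothing
about how often real intervals contain usable shared ancestry.

**Funnel breeding.** Each line runs an independent randomized 8-way
funnel (four F1 crosses, two 4-way crosses, one 8-way sibship) followed
by `g` generations of brother–sister mating, `g ~ U{5..14}` by default
(an incipient panel sampled mid-inbreeding).  Meioses place crossovers as
a Poisson process at 5×10⁻⁹ per bp (~0.5 cM/Mb) with no interference and
no sex-specific or hotspot structure.  Residual heterozygosity is
retained; at `g = 0` it matches an independent single-locus pedigree
Monte-Carlo (tested), and it decays toward fixation as `g` grows.

**Phenotypes.** A planted QTL shifts a line by `0`,
`dominance × effect`, or `effect` according to how many of its haplotypes
at the QTL position come from the functional founder group; default
dominance 0.5 makes heterozygotes exactly intermediate (additive on
diplotypes).  Noise is Gaussian; when a target heritability is given the
noise SD is set from the realized genetic variance so the QTL explains
the requested variance fraction.

## Ancestry HMM

States are ordered founder pairs (8 × 8 = 64).  Transitions factorize per
haplotype: between adjacent SNPs separated by `d` bp a haplotype keeps
its founder with probability `e^{−switch_rate·d}` and otherwise jumps to
a founder drawn uniformly from all eight (the lazy kernel keeps the
uniform distribution stationary; an all-missing stretch therefore relaxes
to dosage 0.25 per founder).  Emissions flip each transmitted allele with
probability `error_rate` (default 0.002); heterozygous or missing founder
calls emit uniformly.  Forward–backward posteriors give expected dosages
(posterior means), which is how heterozygous and uncertain regions enter
the additive regression — the contract keeps row sums exactly 2.
Defaults: `switch_rate = 10⁻⁷`/bp, deliberately above the simulated
recombination density; posteriors are dominated by emissions at desk SNP
densities and accuracy on noiseless mosaics exceeds 99.7% at 10 SNPs/Mb.
Imputation assigns twice the maximum-dosage founder's allele and refuses
to call when the dosage margin is < 0.1 (no fabricated genotypes).
Interval collapsing merges adjacent SNPs where no line's
maximum-posterior unordered pair changes and averages dosages, which is
exactly lossless for the regression wherever dosages are constant within
runs (tested against per-SNP scans).

## Genome scan

Per interval the full model regresses the phenotype on the eight dosage
columns (they sum to 2, so the intercept is absorbed; covariates are
added to both models), and `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`.  Projections
use SVD bases with singular values below 10⁻⁹ of the largest zeroed, so
rank-deficient designs degrade to the pseudo-inverse fit and LOD stays
non-negative.  A perfect fit is capped at LOD 300 (display only); a
numerically constant phenotype gives LOD 0.  Permutation thresholds
shuffle whole phenotype vectors and take the upper empirical
`(1 − α)` order statistic of the genome-wide maximum; the suggestive
threshold is the 90% quantile.  Count-like traits (PLT, WBC, LY, MO, NE)
are `log(x+1)`-transformed before scanning; LOD is invariant to affine
trait maps, so the base does not matter.

**Support intervals.**  The 1.5-LOD interval spans from the first to the
last interval on the peak's chromosome with LOD within 1.5 of the peak.
We evaluated the alternative "widest contiguous run" rule and found it
truncates at single noise dips: on 100 replicates of 200 lines with a
25%-variance QTL it covered the true locus 88 times versus 97–98 for the
span rule, whose median interval (~4 Mb) matches the published scale for
panels of this size.  The span convention is also what the standard
`lodint` implementations report.  For unimodal curves the two rules
coincide.

**Allele effects.**  Minimum-norm least-squares coefficients of the
eight dosage columns at the peak, re-expressed as deviations from the
dosage-weighted population mean.  With 200 lines and a 25%-variance QTL
the per-founder standard error is ≈ 0.7 trait units against a 4-unit
group separation — enough that roughly one replicate in twelve has one
founder's estimate drift across the split (see Grouping below).

## Narrowing

**Grouping.**  Effects are sorted and split at the greatest gap between
consecutive ordered values (ties break to the lowest index and are
flagged).  A founder whose effect lies further than
`ambiguity_ratio × split_gap` (default 0.5) from both group means is
moved to `ambiguous`: it is treated as a possible third allele, and the
shared-ancestry scan is run with it alternately included in each group.
On the validation condition the split never places a founder on the
wrong side (ambiguous founders are unassigned, not misassigned,
100/100); demanding the exact planted bipartition with ambiguity
flagging off succeeds in ~92/100 — the difference is precisely the
replicates where one effect estimate is too noisy to call, which is the
behaviour the ambiguity rule exists to surface.

**Shared-ancestry regions.**  Within the confidence interval, sites
where any group member is het/missing are omitted.  A region is a
maximal run of retained SNPs such that (i) every within-group pairwise
identity over the run is ≥ the threshold (default 0.98), (ii) the run
spans ≥ `min_snps` sites (default 50), and (iii) the run starts and ends
on full-group-match SNPs.  Rule (iii) is the boundary-resolution choice:
a pure fractional threshold lets an L-SNP identical block absorb ~L/49
discordant flanking SNPs before dropping below 0.98, so block boundaries
would be systematically overshot; anchoring regions on concordant sites
recovers planted-block boundaries exactly and equals the brute-force
all-runs oracle.  Identity is the *minimum* pairwise identity within the
group (strictest reading of "share >98%").  Each region carries the
maximum identity of any out-group founder to the group consensus;
regions where that stays below the threshold are flagged exclusive —
the filter for "does not share ancestry with the other allele group".
Raising the threshold never enlarges a region (tested).

**Private SNPs** require every target founder to carry one allele, every
other founder the other, and disqualify any site with a het/missing call
(conservative omission).  **Reduction reports** compute sizes from bp
coordinates (kb/Mb rounded half-up to printed precision) and percent
reduction `100·(1 − candidate/full)` rounded to the nearest percent;
candidate-gene counts use half-open interval overlap.

## Trees

Per-region alignments concatenate founder alleles at fully called SNPs.
Distances are p-distances; trees are neighbor joining (Studier–Keppler
Q), unrooted, negative branch estimates clamped to 0 and flagged.
Distance trees replace model-based maximum likelihood deliberately: the
quantities the pipeline consumes are the topology and bootstrap
supports, NJ is exactly specifiable, and on additive distances it
provably recovers the generating topology (validated on 100 random
8-tip trees, and cross-checked against an independent NJ implementation).
Bootstraps resample alignment columns; support = percentage of
replicates containing each internal bipartition of the full-alignment
tree, written as internal-node labels in the newick.

## Strain statistics

One-way random-effects forms with the harmonic-mean replicate count `n`
for unbalanced designs: `r₁ = (MSB−MSW)/(MSB+(n−1)MSW)` and
`g² = (MSB−MSW)/(MSB+(2n−1)MSW)`; `g²` discounts the doubling of
additive variance among fully inbred strains.  Negative component
estimates truncate to 0 (flagged); `MSW = 0` is the degenerate
perfectly-heritable case.  These are the standard forms for
inbred-strain panels; the exact historical parameterization they stand
in for is not printed anywhere authoritative, so the formulas are
declared here and exposed in the results objects.  Eosinophil/basophil
counts are carried through I/O but excluded from mapping defaults.  The
expression model is OLS of the trait on ΔCt and genotype class (optional
interaction), with single-class and collinearity guards.

## Validation sizes and determinism

All validation runs on one CPU: threshold calibration uses one 100-line
population, a 2000-permutation threshold and 500 fresh null traits;
recovery uses 100 replicates of 200 lines at 1000 mapping loci over a
2×60-Mb genome (≈ 8 intervals/Mb, the per-Mb density of the real
27k-interval mapping sets); block recovery uses 100 planted 1000-SNP
instances with a brute-force oracle on ten of them.  Every stochastic
stage takes an explicit seed; pipeline stage seeds are spawned from one
master seed, and fixed seeds reproduce outputs bit-identically (tested
via artifact checksums).

## Known limitations

Independent-site founder genomes (no background LD), uniform
recombination, no X-specific transmission or parent-of-origin effects,
no kinship or mixed-model correction in the scan, no selection during
inbreeding, and a single-QTL regression (no multi-QTL model selection or
epistasis).  The HMM's exactness claims are relative to this generator;
real array data would add locus-specific error structure the symmetric
emission model ignores.
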