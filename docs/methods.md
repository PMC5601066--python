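# Methods

## The mapping model

`poolscan` targets trait mapping in panels of essentially fully inbred
varieties (selfing crops such as barley), where every line is homozygous at
every marker and a pool of n lines carries exactly n allele observations
per locus. Two sets of `pool_size` varieties are drawn from the tails of
the trait distribution, their DNA notionally pooled and sequenced, and each
biallelic SNP summarised by its per-pool reference allele frequency (RAF),
estimated directly as ref_reads / (ref_reads + alt_reads). The association
statistic is the allele frequency difference

    AFD = RAF_high − RAF_low  ∈  [−1, 1].

A null distribution for AFD is not identifiable from the pools alone (it
depends on the unknown allele frequencies in the source population), so
calling uses a fixed threshold |AFD| > 0.75. The package quantifies what
that threshold implies in the best case: with perfect frequency estimates
and equal source frequencies, a 0.75 difference between pools of 12
corresponds to the line-count table [[12, 0], [3, 9]], Pearson χ² = 14.4 at
1 df, −log10 p ≈ 3.8. Fisher's exact test on the same table gives ≈ 3.5
and a two-proportion normal test ≈ 3.6–3.9; the Pearson construction is
the package convention, and `contrast_table` is exposed so alternative
tests can be applied to the same counts.

### Assumptions

- Fully homozygous lines; no heterozygote codes exist anywhere in the
  pipeline (AFDs move in multiples of 1/pool_size at the line level).
- Equal DNA contribution of every line in a pool, so read sampling is
  binomial around the true pool frequency.
- One biallelic SNP per record; multiallelic sites, indels and MNPs are
  upstream concerns and are skipped on input.

## Set selection

Candidates are ranked by trait mean and admitted greedily from the extreme
inward; a candidate is discarded when its Euclidean genotype distance to
any already admitted line is below `min_distance` (default 20). Alleles
are coded 0/1 for distances, so a squared distance equals the count of
differing markers and the default threshold corresponds to ~400
differences — interpretable against a several-thousand-marker array.
Missing genotypes are handled pairwise-complete with the squared distance
rescaled by n_markers / n_complete (the convention of R's `dist`). Trait
ties at the admission frontier are broken by input order, making selection
deterministic. Forced members (e.g. varieties included for commercial
relevance) are admitted first and exempt from the distance rule;
subsequent candidates are still checked against them.

The structure check tests each marker's allele-by-set 2×2 line-count table
with a Pearson χ² (1 df, no continuity correction) and compares sorted
p-values against a null QQ band. Two envelope modes exist because the
p-values are discrete: with 24 lines a 2×2 table supports only a modest
set of p-values, so the uniform order-statistic band Beta(i, m−i+1)
(`envelope="beta"`, the classical construction and the default) is
systematically escaped by the plateaus of the empirical distribution even
for perfectly null data. `envelope="permutation"` instead draws the band
from random relabelings of set membership, which preserves the discreteness
and is the mode the structure-null tests use. Monomorphic markers within
the selected lines get p = 1 and are flagged rather than dropped.

## Filter cascade

Three pure predicates applied in a fixed order (quality → fixed-allele →
depth) with first-failure attribution, so per-rule exclusion counts sum
with the kept count to the input count while the kept *set* is
order-invariant:

- `min_qual` (default 50): keep iff phred quality ≥ 50 — the literal
  complement of "less than 50 excluded".
- `fixed_raf` (default 0.01): exclude when RAF < 0.01 in **both** pools.
  Such a variant is a fixed difference of both pools against the reference
  genome and carries no contrast information; a variant below 0.01 in only
  one pool is maximally informative, which is why the both-pools reading is
  the default. `fixed_mode="either"` provides the stricter alternative.
- `min_reads` (default 100): keep iff each pool has ≥ 100
  allele-informative reads (ref + alt, not the VCF DP field, since allele
  sampling error is governed by allele-informative reads). Zero-depth
  pools fall under this rule and never cause division errors.

## QTL clustering

Markers passing the threshold are scanned in position order per
chromosome. Two consecutive passing markers join one QTL when their
separation is below the applicable gap; a separation at or above the gap
with no intervening passing marker starts a new QTL. This single-linkage
chaining is the unique partition satisfying the independence rule
literally, and an exhaustive partition search over ≤ 50-marker instances is
used as the test oracle. The gap is 400 Mbp when the span between the two
markers intersects the chromosome's centromere interval and 10 Mbp
otherwise (roughly equal genetic distances in a genome whose recombination
is concentrated distally). The span-intersection rule is a package
convention — the alternative of conditioning on marker location inside the
centromere is nearly equivalent and the gaps are parameters. Chromosomes
missing from the centromere map are treated as non-centromeric with a
warning. Clusters may mix AFD signs by default (the threshold is on
|AFD|); `sign_mode="strict"` splits opposite-sign runs. Peaks are the
member with maximal |AFD|, ties broken by smallest position.

## Validation statistics

- `chisq_homogeneity`: Pearson χ², 1 df, no continuity correction (Yates
  available behind a flag); counting unit is lines, not 2n chromosomes —
  in homozygous material the chromosome convention merely doubles every
  cell and inflates the statistic.
- `chisq_to_neglog10p`: at 1 df computed through the squared-normal
  identity via `norm.logsf`, which stays finite far beyond where the χ²
  survival function underflows.
- `compare_estimated_true`: identity-line R² = 1 − Σ(est−true)² /
  Σ(est−mean(est))², i.e. residuals about y = x rather than a fitted line,
  measuring calibration and not just correlation; plus the Pearson
  correlation of |est| with |true|.
- `allele_trait_ttest`: pooled-variance two-sample t, df = n₁+n₂−2,
  one-sided by default (the discovery contrast fixes which allele is
  "high", so the validation alternative is directional); two-sided
  available.

A practical property of extreme-value selection checked by the test suite:
markers selected for estimated |AFD| > 0.75 overstate their true pool
contrast on average (winner's curse on read-sampling noise), so validation
against individual genotypes should be expected to shrink AFD estimates.

## Synthetic data generator

The generator emulates the study design the analysis assumes: a panel of a
few hundred inbred varieties (default 400), seven 600-Mbp chromosomes with
100-Mbp pericentromeric blocks, ~1000 biallelic markers with founder
reference frequencies Uniform(0.05, 0.95), traits from additive planted
QTL plus Gaussian noise (default SD 10, diastatic-power-like units), pools
of 12, and pooled read counts at Poisson coverage (default mean 275 per
pool per variant, matching a ~275–300× exome regime; negative-binomial
overdispersion available) with per-read base error 0.001 and 1% missing
array genotypes. Missingness is applied after the trait is computed, so
the phenotype reflects true genotypes.

What it does **not** emulate: linkage disequilibrium (markers are
independent draws, so there are no haplotype blocks and QTL intervals are
typically single markers rather than the multi-marker intervals real LD
produces), capture-efficiency autocorrelation along the genome, uneven DNA
contributions of pool members, genotype-by-environment structure, or
reference-mapping bias. Passing recovery tests therefore demonstrates the
statistical machinery — frequency estimation, thresholding, clustering,
calibration — not robustness to those real-data features.

### Acceptance-simulation conditions

The power/false-positive test uses: panel 400, 1000 markers, two planted
QTL with effects of 33 trait units at founder frequencies in [0.3, 0.7]
with noise SD 5 (so each effect ≈ 1.5 total trait SD — the largest
relative effect size two such QTL can jointly have, reachable only toward
the edges of that frequency range), pools of 12, 150× coverage, base error
0.001, distance constraint 10 (inert on an unstructured panel, but
exercised), 20 replicates. Replicate sizes are chosen so the whole suite
runs in seconds while estimates (recovery fraction, mean false-positive
count, identity R² over ~6000 marker-frequency pairs, null exceedance over
~40,000 markers) are stable across seed batches. The null-calibration
check uses eight 5000-marker panels with no planted QTL.

## Numerical choices and degenerate inputs

- Boundary semantics are literal throughout: quality kept at exactly 50,
  depth kept at exactly 100, AFD threshold strict (> 0.75), QTL
  independence at separation ≥ gap, collocation at separation < gap.
- 2×2 tables with a zero marginal: statistic defined as 0, flagged
  degenerate rather than raising.
- A pool with every member missing at a marker yields a flagged
  zero-depth record in simulation and is excluded by the depth filter.
- Variety pairs sharing no complete marker have undefined (NaN) distance;
  the greedy selector skips candidates whose distance to an admitted line
  is undefined.
- All simulation randomness flows from a single integer seed
  (`numpy.random.default_rng`); a fixed seed makes panels, selections and
  written fixture files byte-identical.

## Limitations

- Real Table-style results from the original barley experiment (read
  counts, filtered SNP counts, specific QTL positions) require the archived
  sequencing data and are out of scope; the package validates its arithmetic
  on printed statistic/p-value pairs and its behaviour on simulations.
- The greedy selector is order-dependent by design (it reproduces the
  sequential field protocol), not an optimal diverse-subset solver.
- GFF3 parsing reads the 9-column layout with `ID`/`description`/`Note`/
  `pfam` attributes; it is not a general-purpose GFF toolkit.
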