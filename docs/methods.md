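# Methods

## The statistical problem

Running-sum gene set enrichment analysis tests whether a named subset of
genes is coherently associated with a binary sample phenotype.  Each gene
is scored by a univariate gene–phenotype correlation, genes are ranked by
that score, and the enrichment score (ES) is the signed extremum of a
weighted Kolmogorov–Smirnov-like running sum over the ranking.
Significance comes from a phenotype-permutation null: class labels are
shuffled (class sizes fixed) and the whole statistic recomputed.

The package implements this analysis together with two alternative test
statistics, motivated by an unusual property of the permutation null of
ES: its width is nearly independent of the sample count N.  Shuffled labels
randomize the per-gene correlations regardless of how precisely those
correlations could be estimated, so adding samples narrows the *sampling*
distribution of ES but not its null.  Splitting the cohort into two
stratified halves S1, S2 and averaging their scores,

    ES_avg = 0.5 (ES1 + ES2),

therefore yields a statistic whose null — an average of two draws from a
roughly N-independent null — is markedly narrower than the null of ES at
the same N, while its observed value estimates the same population
quantity.  That width reduction is the entire source of the power gain.
Because ES_avg depends on the particular split, it can be averaged over M
independent random splits,

    <ES_avg> = (1/M) * sum over splits of ES_avg,

which converges (law of large numbers) to a split-free statistic; the
split-to-split spread shrinks with M while the location is unchanged.

## Components

**Gene–phenotype correlation.**  The Mann–Whitney U statistic rescaled to
[-1, 1]: r = 2U/(n_A n_B) − 1, U counting pairs (a, b) with a > b and ties
as one half (mid-rank convention).  r = +1 means complete separation with
higher expression in the first-listed ("positive") class.  The scalar path
delegates to `scipy.stats.mannwhitneyu`.

**Enrichment score.**  Walking genes in order of decreasing r, the running sum
rises by |r_i|^p / N_R at set members (N_R = sum of those weights over the
set) and falls by 1/(n_genes − n_set) elsewhere.  It ends exactly at zero;
ES is the value of largest magnitude, signed.  The weight exponent defaults
to p = 1 and is exposed as a parameter.  When the maximal positive and
negative deviations have exactly equal magnitude the earlier extremum is
reported; this tie has probability zero for continuous data and the
convention is documented rather than load-bearing.

Because the scaled Mann–Whitney correlation lives on a grid (spacing
2/(n_A n_B)), ties across genes are pervasive at small N and the tie order
materially moves the running sum.  Ties in r are broken by descending
between-class mean difference — a continuous, finer-grained association
measure that negates exactly under a class swap, so the ranking of the
swapped problem is the exact mirror and ES → −ES holds exactly — with
ascending gene index only as the final fallback.  Breaking ties by index
alone would sink a set's members to the bottom of their tie groups
whenever they sit late in the gene list, deflating positive extrema and
inflating negative ones.  Rankings remain bit-identical across reruns.

**Splits.**  Halves are stratified by class.  Odd class counts are handled
with ±1 slack: one random draw decides which half receives the first odd
class's extra sample and the second odd class's extra goes to the other
half, so the halves themselves stay equal-sized (within 1 for odd N).
Split draws and permutation draws consume independent named sub-streams of
the user seed, so observed statistics and nulls are reproducible and
mutually uncorrelated, and fresh splits are drawn for every statistic
evaluation — both for observed data and inside every permutation.

**p-values.**  Empirical exceedance against the permutation null.  Default
is the sign-matched tail: null draws sharing the observed sign (zeros count
for both signs), p = #(|null| ≥ |observed|) / #(same-sign null).  A
two-sided option uses all draws.  Zero exceedances are reported as the
bound "< 1/n_perm" rather than 0.

**Permutation engine.**  Permutations never change per-gene expression
ranks, so the engine precomputes the genes × samples mid-rank matrix
(full-cohort correlations for a batch of permutations are then one matrix
product) and a genes × samples × samples pairwise-comparison tensor from
which the U statistic of any subgroup pair is a bilinear form (within-half
ranks cannot be read off full-cohort ranks).  All sums involved are
half-integers, exactly representable, so the fast path is bit-equivalent to
scalar recomputation — a property the test suite asserts at 1e-12.  For
matrices too large for the tensor (~>1.2 GB) a per-half rank recomputation
fallback is used.

## Synthetic benchmark

`splitgsea.synthetic` generates 600-gene datasets from a multivariate
normal with unit variances, by default 25 samples per class: ten
independent blocks combining between-class mean shifts dmu in
{0, 0.1, 0.25, 0.5} (class means ±dmu/2; only the difference matters to a
rank statistic) with within-block correlation rho in {0, 0.6}, one block
holding two 10-gene subgroups with opposite shifts and −0.6 cross-
correlation.  Twenty-one 20-gene benchmark sets (`a`–`u`) mix these blocks;
`a` and `j` are negative controls.  Partial draws from a block take its
lowest-index genes — within a block genes are exchangeable, so the choice
is statistically irrelevant.  Compositions that the benchmark description
leaves open are fixed as: `m` = 7/7/6 from the uncorrelated dmu ladder,
`n` = 7/7/6 from the correlated ladder, `o` = 4/4/3/3/3/3 across both
ladders, `u` = the first gene of each non-null block plus the second gene
of the three uncorrelated ladder blocks.

What the generator emulates: graded effect sizes, inter-gene correlation,
mixed up/down regulation, exactly balanced antagonistic sets.  What it does
not: heavy tails, count noise, normalization artefacts, batch structure,
realistic gene–gene correlation beyond equicorrelated blocks.  Passing the
benchmark shows the statistics behave as designed under Gaussian
exchangeable blocks; it does not by itself certify behaviour on real
expression data.

## Power estimation

Power is the fraction of realizations with permutation p < alpha
(default 0.05).  For synthetic data every realization is a fresh dataset
with a fresh null (a shared-null mode exists for the cohort-subsampling
workflow, where one null per subset size can be reused).  Every proportion
carries its binomial standard error; at 100 realizations that is 0.02–0.05,
which is the resolution at which two statistics can honestly be compared.

Known behaviour worth flagging: for a gene set with *exactly* balanced
up- and down-shifted members of equal strength (set `h`), each half of a
split is equally likely to score positive or negative, the split average
collapses toward zero, and ES_avg/<ES_avg> lose power relative to ES — the
method's documented failure mode.  Significant plain-ES calls on such a set
carry both signs in substantial proportion.  The split is not exactly
50/50 in this benchmark: the many up-shifted non-member genes (the dmu
ladders) crowd the top of the ranking and erode the balanced set's
positive extremum, while its trough region is nearly empty of competitors,
tilting observed ES negative (roughly 30/70 over realizations) — a
property of the benchmark's one-sided design, not of the statistic.

## Problem sizes and numerical choices

Defaults follow the benchmark design: 10,000 permutations, M = 25 splits,
alpha = 0.05, 100 realizations for power grids, 25 + 25 samples.

The test suite and `scripts/acceptance.py` scale permutation counts to the
package's benchmark-run defaults: 2,000 permutations for ES, 1,000 for
ES_avg and 250 for <ES_avg> with M = 25 (each <ES_avg> permutation costs
50 half-cohort evaluations); type-I-error uniformity uses 200 realizations
with 500/400/100 permutations.  At alpha = 0.05 these permutation counts
resolve the rejection decision to well below the binomial noise of 100–200
realizations.  Null-width comparisons keep the full 10,000 permutations.
Kolmogorov–Smirnov uniformity of control-set p-values is tested at
alpha = 0.01; null-width and split-stability comparisons use standard
deviations/IQRs of the stated draw counts.

Numerical notes: running sums close at zero to better than 1e-9 by
construction; engine and scalar paths agree to 1e-12; float32 is used only
for exactly-representable half-integer counts; gene ordering uses a stable
sort on (descending r, ascending index); degenerate inputs (empty
phenotype class, empty gene-set intersection, all-zero in-set correlations,
sets covering every gene) raise informative errors naming the offender.

## Design choices that were genuinely open

- **p-value tail.**  The underlying running-sum methodology scores
  enrichment per sign, so the sign-matched tail is the default; two-sided
  is available as a flag.
- **Observed splits vs null splits.**  The observed <ES_avg> and each
  permutation's <ES_avg> use independent fresh split draws; nothing is
  cached across them.
- **Odd class counts.**  Allowed with ±1 stratification slack (and a logged
  warning on unequal halves) rather than rejected, so arbitrary real
  cohorts work.
- **Gene-set members absent from the dataset** are dropped with a logged
  count (standard GSEA behaviour); matching is case-sensitive.
- **Estimator front end.**  `GeneSetEnrichment` follows scikit-learn
  conventions (`fit(X, y)` with samples × genes input, `get_params`/
  `set_params`, trailing-underscore fitted attributes) so it composes with
  sklearn tooling; the library functions remain the primitive API.

## Limitations

- Binary phenotypes and the scaled Mann–Whitney metric only; continuous
  phenotypes and other correlation metrics are out of scope.
- Splits into more than two parts, normalized enrichment scores,
  leading-edge reporting and cross-set FDR are not implemented.
- Cohort-subsampling power estimates are correlated across realizations
  when the subset size approaches the cohort size.
- The comparison-tensor fast path assumes the genes × samples² tensor fits
  in memory; beyond that the slower per-half fallback engages
  automatically.
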