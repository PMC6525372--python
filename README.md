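# splitgsea

Rank-based gene set enrichment analysis (GSEA) with **split-averaged test
statistics** that increase the statistical power to detect associations
between gene sets and a binary phenotype.

## The problem and who this is for

Running-sum GSEA scores a gene set by the signed extremum of a weighted
Kolmogorov–Smirnov-like walk over genes ranked by their phenotype
correlation, and calibrates it against a phenotype-permutation null.  An
under-appreciated property of that null is that its width barely depends on
the number of samples N: shuffling labels scrambles the gene–phenotype
correlations no matter how many samples went into them.  Extra samples
therefore sharpen the *observed* statistic but not its reference
distribution, and power grows with N more slowly than it could.

`splitgsea` implements, alongside the standard enrichment score ES, two
alternative statistics for bulk or single-cell expression cohorts:

- **ES_avg** — split the cohort into two stratified halves S₁, S₂ and
  average their scores, `ES_avg = ½(ES₁ + ES₂)`.  Each half's null is about
  as wide as the full-cohort null, so the average has a null narrower by
  roughly √2 while estimating the same quantity — more power at the same N.
- **⟨ES_avg⟩** — average ES_avg over M random splits,
  `⟨ES_avg⟩ = Σ_splits ES_avg / M` (default M = 25), removing the
  dependence of the result on any single split.

The null for every statistic is built by shuffling class labels (class
sizes preserved) and re-evaluating the statistic exactly as for observed
data, including fresh stratified splits inside every permutation.  Per-gene
correlations use the Mann–Whitney U statistic rescaled to [−1, 1]; the
running sum weights hits by |r|^p with p = 1 by default.

The package also ships the synthetic benchmark used to validate these
claims — 600-gene block-correlated Gaussian datasets with 21 benchmark gene
sets of graded association strength, correlation structure and up/down
balance — plus power and type-I-error estimation utilities.  It is aimed at
statistical bioinformaticians who want either a drop-in enrichment test
with better power characteristics or a reproducible harness for studying
enrichment-statistic behaviour.

## Worked example

```python
import splitgsea as sg

# one synthetic benchmark realization: 600 genes, 25 + 25 samples
ds = sg.simulate_dataset(25, random_state=0)
sets = sg.gene_set_catalogue().collection()   # benchmark sets a..u

results = sg.enrichment_analysis(
    ds, sets,
    spec=sg.StatisticSpec("es-avg-multi", n_splits=25),
    n_perm=1000, random_state=0,
)
for r in results:
    if r.gene_set in "abch":
        print(r.gene_set, round(r.observed, 3), str(r.p))
```

prints

```
a -0.015 0.951807
b 0.659 < 0.001
c 0.452 0.00384615
h -0.076 0.701461
```

Read: control set `a` (no association) scores ⟨ES_avg⟩ ≈ 0 with a null
p-value; `b` (20 genes shifted by 0.5 sd) is enriched toward the first
phenotype class with p below the permutation resolution 1/1000; `c` (shift
0.25 sd) is clearly detected; `h` — ten genes up and ten down with equal
strength — collapses toward zero under split averaging, the method's
documented failure mode (plain ES detects it more often).

The same analysis is available as a scikit-learn style estimator on
samples × genes arrays:

```python
from splitgsea import GeneSetEnrichment
model = GeneSetEnrichment(gene_sets={"myset": ["TP53", "BRCA1"]},
                          statistic="es-avg", n_permutations=10_000,
                          random_state=0)
model.fit(X, y)          # X: samples x genes DataFrame, y: binary labels
model.results_           # observed statistic, p-value per gene set
```

and from the shell, on GCT/CLS/GMT files:

```bash
splitgsea simulate --out-dir data --seed 0
splitgsea enrich --expression data/synthetic_000.gct \
                 --phenotype data/synthetic_000.cls \
                 --gene-sets data/benchmark_sets.gmt \
                 --statistic es-avg-multi --n-splits 25 \
                 --n-perm 10000 --seed 0 --out results.tsv
splitgsea benchmark --n-realizations 100 --seed 0 --out table.tsv
```

Positive statistics always mean enrichment toward the first-listed
phenotype class; every output file's header records seed, statistic and
permutation count.

## Scope

Binary phenotypes, two-way splits, raw permutation p-values.  Normalized
enrichment scores, FDR across collections, leading-edge subsets,
multi-part splits and continuous phenotypes are out of scope.
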