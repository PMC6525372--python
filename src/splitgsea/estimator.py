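"""scikit-learn style front end for the enrichment analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import rank_genes
from .datasets import ExpressionDataset, GeneSetCollection
from .permutation import enrichment_analysis
from .splits import StatisticSpec


class GeneSetEnrichment(BaseEstimator):
    """Rank-based gene set enrichment with permutation p-values.

    Fits no model in the predictive sense: ``fit(X, y)`` runs the enrichment
    analysis of the binary phenotype ``y`` against each configured gene set
    and stores the per-set results.

    Parameters
    ----------
    gene_sets : mapping or GeneSetCollection
        Named gene sets; members refer to feature (gene) names.
    statistic : {"es", "es-avg", "es-avg-multi"}
        Whole-cohort enrichment score, its average over one stratified
        half-split of the samples, or that average over ``n_splits`` random
        splits.
    n_splits : int
        Number of random splits M for ``es-avg-multi``.
    n_permutations : int
        Phenotype permutations used for the null distribution.
    weight_exponent : float
        Exponent p on |correlation| weighting the running sum (default 1).
    alternative : {"sign-matched", "two-sided"}
        Tail convention for the empirical p-value.
    random_state : int, SeedSequence, Generator or None
        Seeds both the split draws and the permutations.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene set: observed statistic, p-value, display string.
    ranking_ : CorrelationRanking
        Whole-cohort gene ranking (descending scaled Mann-Whitney r; r > 0
        means higher expression in the positive class).
    classes_ : ndarray of shape (2,)
        Phenotype classes; ``classes_[0]`` is the positive direction.

    Examples
    --------
    >>> import numpy as np
    >>> from splitgsea import GeneSetEnrichment
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(20, 30))
    >>> X[:10, :5] += 1.0                      # first 5 genes shifted in class "A"
    >>> y = np.array(["A"] * 10 + ["B"] * 10)
    >>> model = GeneSetEnrichment(
    ...     gene_sets={"shifted": [f"g{i}" for i in range(5)]},
    ...     n_permutations=200, random_state=0)
    >>> model.fit(X, y).results_.iloc[0]["p_value"] < 0.1
    True
    """

    def __init__(
        self,
        gene_sets=None,
        statistic: str = "es",
        n_splits: int = 25,
        n_permutations: int = 10_000,
        weight_exponent: float = 1.0,
        alternative: str = "sign-matched",
        random_state=None,
    ):
        self.gene_sets = gene_sets
        self.statistic = statistic
        self.n_splits = n_splits
        self.n_permutations = n_permutations
        self.weight_exponent = weight_exponent
        self.alternative = alternative
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _spec(self) -> StatisticSpec:
        n_splits = self.n_splits if self.statistic == "es-avg-multi" else 1
        return StatisticSpec(
            kind=self.statistic,
            n_splits=n_splits,
            weight_exponent=self.weight_exponent,
        )

    def _dataset(self, X, y) -> ExpressionDataset:
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            sample_ids = [str(i) for i in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-D (samples x genes)")
            gene_ids = [f"g{i}" for i in range(values.shape[1])]
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        y = np.asarray(y)
        if y.shape[0] != values.shape[0]:
            raise ValueError("y length must match the number of samples in X")
        # positive direction = first-appearance order of y
        _, first = np.unique(y, return_index=True)
        classes = y[np.sort(first)]
        return ExpressionDataset(
            gene_ids=gene_ids,
            values=values.T,
            sample_ids=sample_ids,
            phenotype=y,
            classes=tuple(classes),
        )

    def fit(self, X, y):
        """Run the enrichment analysis of ``y`` against every gene set."""
        if self.gene_sets is None or len(self.gene_sets) == 0:
            raise ValueError("gene_sets must be provided")
        if isinstance(self.gene_sets, GeneSetCollection):
            collection = self.gene_sets
        else:
            collection = GeneSetCollection.from_dict(self.gene_sets)
        dataset = self._dataset(X, y)
        spec = self._spec()
        results = enrichment_analysis(
            dataset,
            collection,
            spec=spec,
            n_perm=self.n_permutations,
            alternative=self.alternative,
            random_state=self.random_state,
        )
        self.classes_ = np.asarray(dataset.classes)
        self.n_features_in_ = dataset.n_genes
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.ranking_ = rank_genes(dataset)
        self.results_ = pd.DataFrame(
            {
                "gene_set": [r.gene_set for r in results],
                "statistic": spec.kind,
                "n_splits": spec.effective_splits,
                "observed": [r.observed for r in results],
                "p_value": [r.p.value for r in results],
                "p_display": [str(r.p) for r in results],
                "n_perm": self.n_permutations,
            }
        )
        return self

    # ------------------------------------------------------------------
    def significant_sets(self, alpha: float = 0.05) -> pd.DataFrame:
        """Rows of ``results_`` with p-value below ``alpha``."""
        check_is_fitted(self, "results_")
        return self.results_[self.results_["p_value"] < alpha]
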