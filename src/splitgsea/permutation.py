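"""Phenotype-permutation null distributions and empirical p-values.

Each permutation shuffles the sample class labels (class sizes preserved)
and re-evaluates the chosen statistic exactly as for the observed data —
including drawing fresh stratified splits from the shuffled labels for the
split statistics.  Per-gene expression ranks are computed once per dataset
and only re-aggregated over the shuffled labels, which is mathematically
identical to recomputing from scratch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._engine import (
    RankEngine,
    enrichment_scores,
    permutation_masks,
    split_half_masks,
)
from ._random import as_generator, substreams
from .datasets import ExpressionDataset, GeneSet, GeneSetCollection
from .splits import StatisticSpec

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class NullDistribution:
    """Permutation draws of a statistic for one gene set."""

    values: np.ndarray
    spec: StatisticSpec
    n_perm: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.shape != (self.n_perm,):
            raise ValueError("null length must equal n_perm")

    def std(self) -> float:
        return float(np.std(self.values, ddof=1))

    def iqr(self) -> float:
        q1, q3 = np.percentile(self.values, [25, 75])
        return float(q3 - q1)

    def p_value(self, observed: float, alternative: str = "sign-matched"):
        return p_value(observed, self, alternative=alternative)


@dataclass(frozen=True)
class PermutationPValue:
    """Empirical permutation p-value with its exceedance bookkeeping.

    ``value`` is the exceedance proportion; when no null draw reaches the
    observed statistic the p-value is only bounded above by ``1 / n_perm``
    (``is_bound`` is then True and ``value`` is 0.0; display as
    ``< 1/n_perm``).
    """

    count: int
    denominator: int
    n_perm: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return 0.0
        return self.count / self.denominator

    @property
    def is_bound(self) -> bool:
        return self.count == 0

    def __float__(self) -> float:
        return self.value

    def __str__(self) -> str:
        if self.is_bound:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.value:.6g}"


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's observed statistic and permutation p-value."""

    gene_set: str
    observed: float
    p: PermutationPValue
    spec: StatisticSpec
    n_perm: int
    null: NullDistribution | None = field(default=None, repr=False)


def p_value(
    observed: float, null: NullDistribution | np.ndarray, alternative: str = "sign-matched"
) -> PermutationPValue:
    """Empirical p-value of an observed statistic against permutation draws.

    ``sign-matched`` (default): restrict the null to draws sharing the sign
    of the observed statistic (zeros count toward both signs) and report the
    proportion at least as extreme in magnitude.  ``two-sided``: proportion
    of all draws with ``|null| >= |observed|``.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    n_perm = values.size
    if n_perm == 0:
        raise ValueError("empty null distribution")
    if alternative == "two-sided":
        count = int((np.abs(values) >= abs(observed)).sum())
        return PermutationPValue(count=count, denominator=n_perm, n_perm=n_perm)
    if alternative != "sign-matched":
        raise ValueError(f"unknown alternative {alternative!r}")
    if observed >= 0:
        same = values[values >= 0]
    else:
        same = values[values <= 0]
    denom = same.size
    if denom == 0:
        logger.warning(
            "no permutation draw shares the observed sign; reporting p < 1/n_perm"
        )
        return PermutationPValue(count=0, denominator=0, n_perm=n_perm)
    count = int((np.abs(same) >= abs(observed)).sum())
    return PermutationPValue(count=count, denominator=denom, n_perm=n_perm)


def _member_matrix(dataset: ExpressionDataset, gene_sets) -> tuple[list[str], np.ndarray]:
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    gene_sets = list(gene_sets)
    names = [gs.name for gs in gene_sets]
    masks = np.stack([gs.member_mask(dataset) for gs in gene_sets])
    return names, masks


def null_statistic_matrix(
    dataset: ExpressionDataset,
    gene_sets,
    spec: StatisticSpec,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    random_state=None,
    engine: RankEngine | None = None,
    perm_batch: int = 256,
) -> tuple[list[str], np.ndarray]:
    """Null draws for several gene sets sharing the same permutations.

    Returns ``(names, values)`` with ``values`` of shape
    ``(n_sets, n_perm)``.  The expensive per-permutation work (correlations
    and the gene ordering) is shared across gene sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng_perm, rng_split = substreams(random_state, 2)
    if engine is None:
        engine = RankEngine(dataset.values)
    names, masks = _member_matrix(dataset, gene_sets)
    pos = dataset.positive_mask
    out = np.empty((len(names), n_perm), float)

    if spec.kind == "es":
        perms = permutation_masks(pos, n_perm, rng_perm)
        r = engine.correlations_labeled(perms)
        md = engine.mean_diff(perms, ~perms)
        out[:] = enrichment_scores(r, masks, spec.weight_exponent, tie_break=md)
        return names, out

    m = spec.effective_splits
    batch = max(1, min(perm_batch, int(4.0e5 // max(1, 2 * m))))
    for p0 in range(0, n_perm, batch):
        p1 = min(n_perm, p0 + batch)
        k = p1 - p0
        perms = permutation_masks(pos, k, rng_perm)
        s1 = split_half_masks(perms, m, rng_split)
        pos_rep = np.repeat(perms, m, axis=1)
        a_mask = np.concatenate([pos_rep & s1, pos_rep & ~s1], axis=1)
        b_mask = np.concatenate([~pos_rep & s1, ~pos_rep & ~s1], axis=1)
        r = engine.correlations_within(a_mask, b_mask)
        md = engine.mean_diff(a_mask, b_mask)
        es = enrichment_scores(r, masks, spec.weight_exponent, tie_break=md)
        halves = es.reshape(len(names), 2, k, m)
        out[:, p0:p1] = halves.mean(axis=(1, 3))
    return names, out


def null_distribution(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    spec: StatisticSpec = StatisticSpec("es"),
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    random_state=None,
    engine: RankEngine | None = None,
) -> NullDistribution:
    """Phenotype-permutation null of one statistic for one gene set."""
    _, values = null_statistic_matrix(
        dataset, gene_set, spec, n_perm, random_state, engine
    )
    return NullDistribution(values=values[0], spec=spec, n_perm=n_perm)


def null_width_summary(null: NullDistribution, bins: int = 40) -> dict:
    """Descriptive width summary of a null (st.dev., IQR, histogram)."""
    if null.n_perm < 100:
        raise ValueError("need at least 100 permutations for a width summary")
    hist, edges = np.histogram(null.values, bins=bins)
    return {
        "std": null.std(),
        "iqr": null.iqr(),
        "histogram": (hist, edges),
    }


def count_histogram_modes(values: np.ndarray, bins: int = 25, smooth: int = 3) -> int:
    """Crude multimodality probe: local maxima of a smoothed histogram.

    Used to verify that the ES_avg null's multi-peak structure (ES1 and ES2
    carry random signs under permutation) washes out as splits are averaged.
    """
    hist, _ = np.histogram(values, bins=bins, density=True)
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(hist, kernel, mode="same")
    modes = 0
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] > left and sm[i] >= right and sm[i] > 0.05 * sm.max():
            modes += 1
    return modes


def enrichment_analysis(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection,
    spec: StatisticSpec = StatisticSpec("es"),
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    alternative: str = "sign-matched",
    random_state=None,
    keep_null: bool = False,
) -> list[EnrichmentResult]:
    """Observed statistic + permutation p-value for each gene set.

    The observed statistic's split draws and the null's split draws are
    independent streams derived from ``random_state``.
    """
    from .splits import evaluate_statistic

    rng_obs, rng_null = substreams(random_state, 2)
    engine = RankEngine(dataset.values)
    names, nulls = null_statistic_matrix(
        dataset, list(gene_sets), spec, n_perm, rng_null, engine
    )
    results = []
    for i, gs in enumerate(gene_sets):
        observed = evaluate_statistic(dataset, gs, spec, random_state=rng_obs)
        nd = NullDistribution(values=nulls[i], spec=spec, n_perm=n_perm)
        pv = p_value(observed, nd, alternative=alternative)
        results.append(
            EnrichmentResult(
                gene_set=names[i],
                observed=observed,
                p=pv,
                spec=spec,
                n_perm=n_perm,
                null=nd if keep_null else None,
            )
        )
    return results
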