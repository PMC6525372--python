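"""Split-averaged enrichment statistics.

``ES_avg`` halves the cohort into two stratified subgroups S1, S2 and
averages their enrichment scores, ``0.5 (ES1 + ES2)``.  Averaging ES_avg over
M independent random splits gives ``<ES_avg>``, which removes the dependence
of the statistic on any particular split: by the law of large numbers the
split-to-split spread shrinks while the location is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._engine import RankEngine, enrichment_scores, split_half_masks
from ._random import as_generator
from .core import enrichment_score, rank_genes
from .datasets import DegeneratePhenotypeError, ExpressionDataset, GeneSet

logger = logging.getLogger(__name__)

STATISTIC_KINDS = ("es", "es-avg", "es-avg-multi")


@dataclass(frozen=True)
class StatisticSpec:
    """Which enrichment statistic to evaluate, and its randomness contract.

    ``kind`` is one of ``es`` (whole-cohort ES), ``es-avg`` (one stratified
    half-split), ``es-avg-multi`` (mean of ES_avg over ``n_splits`` random
    splits).  ``es-avg-multi`` with ``n_splits=1`` is exactly ``es-avg``.
    """

    kind: str = "es"
    n_splits: int = 1
    weight_exponent: float = 1.0

    def __post_init__(self):
        if self.kind not in STATISTIC_KINDS:
            raise ValueError(
                f"unknown statistic kind {self.kind!r}; expected one of "
                f"{STATISTIC_KINDS}"
            )
        if self.kind == "es-avg-multi" and self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    @property
    def effective_splits(self) -> int:
        """Number of half-splits one evaluation consumes (0 for plain ES)."""
        if self.kind == "es":
            return 0
        if self.kind == "es-avg":
            return 1
        return self.n_splits

    @property
    def label(self) -> str:
        if self.kind == "es":
            return "ES"
        if self.kind == "es-avg":
            return "ES_avg"
        return f"<ES_avg> (M={self.n_splits})"


@dataclass(frozen=True)
class SplitScheme:
    """A reusable batch of M half-splits of one cohort.

    Each split is a pair of disjoint sample-id groups covering the cohort,
    with per-class counts differing by at most one between the halves.
    """

    splits: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "splits", tuple((tuple(s1), tuple(s2)) for s1, s2 in self.splits)
        )
        for s1, s2 in self.splits:
            if set(s1) & set(s2):
                raise ValueError("split halves overlap")
            if abs(len(s1) - len(s2)) > 1:
                raise ValueError("split halves differ by more than one sample")

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    @classmethod
    def draw(cls, dataset: ExpressionDataset, n_splits: int, random_state=None):
        rng = as_generator(random_state)
        return cls(
            splits=[
                stratified_split(dataset.sample_ids, dataset.phenotype, rng)
                for _ in range(n_splits)
            ]
        )


def stratified_split(sample_ids, labels, random_state=None):
    """Randomly halve a cohort, stratifying by class.

    Each class is divided as evenly as possible between the halves; when both
    class counts are odd, one random draw decides which half receives class
    A's extra sample and class B's extra goes to the other half, keeping the
    halves equal in size.  Deterministic given the random state.

    Returns ``(s1_ids, s2_ids)`` as lists.
    """
    rng = as_generator(random_state)
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    classes, first = np.unique(labels, return_index=True)
    classes = classes[np.argsort(first)]
    counts = {c: int((labels == c).sum()) for c in classes}
    for c, cnt in counts.items():
        if cnt < 2:
            raise DegeneratePhenotypeError(
                f"class {c!r} has {cnt} sample(s); need >= 2 to split"
            )
    draw = int(rng.integers(0, 2))
    odd = [c for c in classes if counts[c] % 2 == 1]
    s1: list = []
    s2: list = []
    for c in classes:
        members = [s for s, l in zip(sample_ids, labels) if l == c]
        members = [members[i] for i in rng.permutation(len(members))]
        take = counts[c] // 2
        if counts[c] % 2 == 1:
            if len(odd) == 2 and c == odd[1]:
                take += 1 - draw  # opposite half from the first odd class
            else:
                take += draw
        s1.extend(members[:take])
        s2.extend(members[take:])
    if len(s1) != len(s2):
        logger.warning(
            "unequal split halves (%d vs %d) for odd cohort size", len(s1), len(s2)
        )
    return s1, s2


def es_avg(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    split: tuple | None = None,
    random_state=None,
    weight_exponent: float = 1.0,
) -> float:
    """ES averaged over one stratified half-split: ``0.5 (ES1 + ES2)``.

    If ``split`` (a pair of sample-id sequences) is not given, one is drawn
    from ``random_state``.
    """
    if split is None:
        split = stratified_split(dataset.sample_ids, dataset.phenotype, random_state)
    s1, s2 = split
    scores = []
    for half in (s1, s2):
        sub = dataset.subset_samples(np.asarray(list(half)))
        ranking = rank_genes(sub)
        es, _ = enrichment_score(ranking, gene_set, weight_exponent, dataset=sub)
        scores.append(es)
    return 0.5 * (scores[0] + scores[1])


def es_avg_multi(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    n_splits: int,
    random_state=None,
    weight_exponent: float = 1.0,
    scheme: SplitScheme | None = None,
) -> float:
    """Mean of ES_avg over ``n_splits`` independent stratified splits.

    A precomputed :class:`SplitScheme` may be supplied to evaluate several
    gene sets on identical splits; otherwise fresh splits are drawn.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if scheme is None:
        rng = as_generator(random_state)
        scheme = SplitScheme.draw(dataset, n_splits, rng)
    elif len(scheme) != n_splits:
        raise ValueError("scheme size does not match n_splits")
    values = [
        es_avg(dataset, gene_set, split=split, weight_exponent=weight_exponent)
        for split in scheme
    ]
    return float(np.mean(values))


def evaluate_statistic(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    spec: StatisticSpec,
    random_state=None,
) -> float:
    """Evaluate one observed statistic on the dataset's true labels."""
    if spec.kind == "es":
        ranking = rank_genes(dataset)
        es, _ = enrichment_score(
            ranking, gene_set, spec.weight_exponent, dataset=dataset
        )
        return es
    return es_avg_multi(
        dataset,
        gene_set,
        spec.effective_splits,
        random_state=random_state,
        weight_exponent=spec.weight_exponent,
    )


def split_sampling_distribution(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    n_splits: int,
    n_draws: int,
    random_state=None,
    weight_exponent: float = 1.0,
    engine: RankEngine | None = None,
) -> np.ndarray:
    """Distribution of ``<ES_avg>`` over independent sets of random splits.

    Evaluates the statistic ``n_draws`` times on the *true* labels, each time
    with a fresh batch of ``n_splits`` stratified splits; used to study how
    the split-choice variability shrinks with M.
    """
    rng = as_generator(random_state)
    if engine is None:
        engine = RankEngine(dataset.values)
    member = gene_set.member_mask(dataset)
    pos = dataset.positive_mask[:, None]
    out = np.empty(n_draws, float)
    # batch draws to bound memory: each draw costs 2 * n_splits columns
    batch = max(1, int(2.0e5 // max(1, 2 * n_splits)))
    for d0 in range(0, n_draws, batch):
        d1 = min(n_draws, d0 + batch)
        k = d1 - d0
        s1 = split_half_masks(np.repeat(pos, k, axis=1), n_splits, rng)
        pos_rep = np.repeat(pos, k * n_splits, axis=1)
        a_mask = np.concatenate([pos_rep & s1, pos_rep & ~s1], axis=1)
        b_mask = np.concatenate([~pos_rep & s1, ~pos_rep & ~s1], axis=1)
        r = engine.correlations_within(a_mask, b_mask)
        md = engine.mean_diff(a_mask, b_mask)
        es = enrichment_scores(r, member, weight_exponent, tie_break=md)[0]
        halves = es.reshape(2, k, n_splits)
        out[d0:d1] = halves.mean(axis=(0, 2))
    return out
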