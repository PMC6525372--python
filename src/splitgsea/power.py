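"""Power and sampling-distribution estimation.

Power is the proportion of data realizations whose permutation p-value
falls below the significance level alpha.  Realizations are either fresh
synthetic datasets or stratified random subsets of one fixed cohort; the
latter are correlated with each other for subset sizes close to the cohort
size, which the estimates inherit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import RankEngine
from ._random import as_generator, as_seed_sequence
from .datasets import ExpressionDataset, GeneSet
from .permutation import (
    DEFAULT_N_PERMUTATIONS,
    NullDistribution,
    null_statistic_matrix,
    p_value,
)
from .splits import StatisticSpec, evaluate_statistic
from .synthetic import SyntheticCatalogue, gene_set_catalogue, simulate_dataset


@dataclass(frozen=True)
class PowerEstimate:
    """Detection proportion at level alpha with its binomial standard error."""

    gene_set: str
    spec: StatisticSpec
    alpha: float
    n_realizations: int
    proportion: float

    @property
    def se(self) -> float:
        p = self.proportion
        return float(np.sqrt(p * (1.0 - p) / self.n_realizations))


def draw_subset(
    dataset: ExpressionDataset, n: int, random_state=None
) -> ExpressionDataset:
    """Random stratified subset of ``n`` samples from a cohort.

    Class proportions are preserved as closely as possible (largest
    remainder rounding); each class keeps at least 2 samples.
    """
    rng = as_generator(random_state)
    if n > dataset.n_samples:
        raise ValueError("subset size exceeds the cohort size")
    pos = dataset.positive_mask
    counts = np.array([int(pos.sum()), int((~pos).sum())])
    exact = n * counts / counts.sum()
    take = np.floor(exact).astype(int)
    rem = np.argsort(-(exact - take))
    for i in range(n - take.sum()):
        take[rem[i % 2]] += 1
    if (take < 2).any():
        raise ValueError(
            f"subset of {n} leaves a phenotype class with fewer than 2 samples"
        )
    idx_pos = np.flatnonzero(pos)
    idx_neg = np.flatnonzero(~pos)
    chosen = np.concatenate(
        [
            rng.choice(idx_pos, size=take[0], replace=False),
            rng.choice(idx_neg, size=take[1], replace=False),
        ]
    )
    return dataset.subset_samples(np.sort(chosen))


def benchmark_power(
    gene_sets=None,
    specs=(StatisticSpec("es"),),
    n_realizations: int = 100,
    n_perm: int | dict = DEFAULT_N_PERMUTATIONS,
    alpha: float = 0.05,
    n_per_class: int = 25,
    random_state=None,
    catalogue: SyntheticCatalogue | None = None,
    return_records: bool = False,
):
    """Synthetic power grid: gene sets x statistics.

    For each realization a fresh synthetic dataset is simulated, the
    observed statistic evaluated, and a fresh permutation null generated
    (``n_perm`` may be a dict keyed by statistic kind).  Returns a tidy
    DataFrame with one row per (gene set, statistic); with
    ``return_records=True`` also the per-realization observed statistics and
    p-values.
    """
    cat = catalogue or gene_set_catalogue()
    collection = cat.collection()
    if gene_sets is None:
        names = collection.names
    else:
        names = [gs if isinstance(gs, str) else gs.name for gs in gene_sets]
    sets = [collection[name] for name in names]
    specs = list(specs)

    ss = as_seed_sequence(random_state)
    records = []
    for real_idx, child in enumerate(ss.spawn(n_realizations)):
        rng_data, rng_obs, rng_null = (np.random.default_rng(c) for c in child.spawn(3))
        ds = simulate_dataset(n_per_class, rng_data, catalogue=cat)
        engine = RankEngine(ds.values)
        for spec in specs:
            np_spec = n_perm[spec.kind] if isinstance(n_perm, dict) else n_perm
            _, nulls = null_statistic_matrix(
                ds, sets, spec, np_spec, rng_null, engine
            )
            for i, gs in enumerate(sets):
                observed = evaluate_statistic(ds, gs, spec, random_state=rng_obs)
                pv = p_value(observed, nulls[i])
                records.append(
                    {
                        "realization": real_idx,
                        "gene_set": gs.name,
                        "statistic": spec.kind,
                        "n_splits": spec.effective_splits,
                        "observed": observed,
                        "p_value": pv.value,
                        "p_is_bound": pv.is_bound,
                        "n_perm": np_spec,
                        "significant": pv.value < alpha,
                    }
                )
    rec = pd.DataFrame.from_records(records)
    grouped = (
        rec.groupby(["gene_set", "statistic", "n_splits"], sort=False)["significant"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "power", "size": "n_realizations"})
    )
    grouped["se"] = np.sqrt(
        grouped["power"] * (1 - grouped["power"]) / grouped["n_realizations"]
    )
    grouped["alpha"] = alpha
    if return_records:
        return grouped, rec
    return grouped


def estimate_power_synthetic(
    gene_set: str | GeneSet,
    spec: StatisticSpec,
    n_realizations: int = 100,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = 0.05,
    random_state=None,
    n_per_class: int = 25,
    catalogue: SyntheticCatalogue | None = None,
) -> PowerEstimate:
    """Power of one statistic for one benchmark gene set (synthetic data)."""
    table = benchmark_power(
        gene_sets=[gene_set],
        specs=[spec],
        n_realizations=n_realizations,
        n_perm=n_perm,
        alpha=alpha,
        n_per_class=n_per_class,
        random_state=random_state,
        catalogue=catalogue,
    )
    return PowerEstimate(
        gene_set=table["gene_set"].iloc[0],
        spec=spec,
        alpha=alpha,
        n_realizations=int(table["n_realizations"].iloc[0]),
        proportion=float(table["power"].iloc[0]),
    )


def estimate_power_subsampling(
    cohort: ExpressionDataset,
    gene_set: GeneSet,
    spec: StatisticSpec,
    n: int,
    n_realizations: int = 100,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = 0.05,
    random_state=None,
    shared_null: bool = False,
) -> PowerEstimate:
    """Power over stratified subsets of size ``n`` from one fixed cohort.

    With ``shared_null=True`` a single permutation null (from the first
    subset drawn) is reused for every realization, matching workflows that
    precompute one null per subset size; otherwise each realization gets a
    fresh null from its own subset.
    """
    ss = as_seed_sequence(random_state)
    hits = 0
    shared: NullDistribution | None = None
    for child in ss.spawn(n_realizations):
        rng_sub, rng_obs, rng_null = (np.random.default_rng(c) for c in child.spawn(3))
        sub = draw_subset(cohort, n, rng_sub)
        observed = evaluate_statistic(sub, gene_set, spec, random_state=rng_obs)
        if shared_null and shared is not None:
            nd = shared
        else:
            _, nulls = null_statistic_matrix(sub, gene_set, spec, n_perm, rng_null)
            nd = NullDistribution(values=nulls[0], spec=spec, n_perm=n_perm)
            if shared_null:
                shared = nd
        if p_value(observed, nd).value < alpha:
            hits += 1
    return PowerEstimate(
        gene_set=gene_set.name,
        spec=spec,
        alpha=alpha,
        n_realizations=n_realizations,
        proportion=hits / n_realizations,
    )
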