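"""Permutation nulls, p-values, and the vectorized engine's exactness."""

import numpy as np
import pytest

import splitgsea as sg
from splitgsea._engine import (
    RankEngine,
    enrichment_scores,
    permutation_masks,
    split_half_masks,
)
from splitgsea.core import CorrelationRanking

from conftest import random_small_dataset


def test_p_value_sign_matched_enumeration():
    null = np.array([-0.5, -0.2, 0.1, 0.3, 0.9])
    pv = sg.p_value(0.3, null)
    assert pv.value == pytest.approx(2 / 3)
    assert not pv.is_bound


def test_p_value_bound_when_observed_exceeds_all():
    null = np.array([-0.5, -0.2, 0.1, 0.3, 0.9])
    pv = sg.p_value(0.95, null)
    assert pv.is_bound
    assert str(pv) == "< 0.2"
    assert pv.value == 0.0


def test_p_value_two_sided():
    null = np.array([-0.5, -0.2, 0.1, 0.3, 0.9])
    pv = sg.p_value(0.3, null, alternative="two-sided")
    assert pv.value == pytest.approx(3 / 5)


def test_p_value_empty_null_rejected():
    with pytest.raises(ValueError):
        sg.p_value(0.1, np.array([]))


def test_permutation_masks_preserve_class_sizes():
    rng = np.random.default_rng(0)
    pos = np.array([True] * 7 + [False] * 13)
    masks = permutation_masks(pos, 200, rng)
    assert masks.shape == (20, 200)
    assert (masks.sum(axis=0) == 7).all()


def test_split_half_masks_are_stratified_partitions():
    rng = np.random.default_rng(1)
    pos = np.zeros((50, 30), dtype=bool)
    pos[:25] = True
    s1 = split_half_masks(pos, 4, rng)
    assert s1.shape == (50, 120)
    assert (s1.sum(axis=0) == 25).all()
    pos_rep = np.repeat(pos, 4, axis=1)
    in_a = (s1 & pos_rep).sum(axis=0)
    assert np.isin(in_a, (12, 13)).all()
    # extras are not systematically assigned to one half
    assert len(np.unique(in_a)) == 2


def test_engine_full_correlations_match_scalar():
    rng = np.random.default_rng(10)
    for _ in range(10):
        ds = random_small_dataset(rng)
        engine = RankEngine(ds.values)
        r = engine.correlations_labeled(ds.positive_mask[:, None])[:, 0]
        np.testing.assert_allclose(r, sg.rank_genes(ds).correlations, atol=1e-12)


@pytest.mark.parametrize("force_slow", [False, True])
def test_engine_half_correlations_match_scalar(force_slow):
    """Subgroup correlations from the comparison tensor equal per-half
    recomputation, both with and without the tensor fast path."""
    rng = np.random.default_rng(11)
    for trial in range(8):
        ds = random_small_dataset(rng, n_genes=10, n_per_class=int(rng.integers(4, 8)))
        engine = RankEngine(ds.values)
        if force_slow:
            engine.MAX_CMP_BYTES = 0
        s1, _ = sg.stratified_split(ds.sample_ids, ds.phenotype, random_state=trial)
        half = np.isin(np.array(ds.sample_ids), s1)
        a = (ds.positive_mask & half)[:, None]
        b = (~ds.positive_mask & half)[:, None]
        r = engine.correlations_within(a, b)[:, 0]
        sub = ds.subset_samples(half)
        np.testing.assert_allclose(r, sg.rank_genes(sub).correlations, atol=1e-12)


def test_engine_enrichment_scores_match_scalar():
    rng = np.random.default_rng(12)
    for _ in range(10):
        ds = random_small_dataset(rng, n_genes=15)
        r = sg.rank_genes(ds).correlations
        members = np.zeros(15, dtype=bool)
        members[rng.choice(15, size=5, replace=False)] = True
        if not np.any(np.abs(r[members]) > 0):
            continue
        vec = enrichment_scores(r[:, None], members)[0, 0]
        ranking = CorrelationRanking(r, np.argsort(-r, kind="stable"))
        scalar, _ = sg.enrichment_score(ranking, np.flatnonzero(members))
        assert vec == pytest.approx(scalar, abs=1e-12)


def test_null_distribution_basic_properties(small_dataset, collection):
    nd = sg.null_distribution(
        small_dataset,
        collection["b"],
        sg.StatisticSpec("es"),
        n_perm=500,
        random_state=3,
    )
    assert nd.n_perm == 500
    assert np.all(np.abs(nd.values) <= 1.0)
    summary = sg.null_width_summary(nd)
    assert summary["std"] > 0
    assert summary["iqr"] > 0
    hist, edges = summary["histogram"]
    assert hist.sum() == 500


def test_null_width_summary_needs_enough_draws():
    nd = sg.NullDistribution(np.zeros(50), sg.StatisticSpec("es"), 50)
    with pytest.raises(ValueError):
        sg.null_width_summary(nd)
    assert nd.std() == 0.0


def test_es_avg_null_loses_multimodality_with_m(collection):
    """The ES_avg null has side peaks (ES1/ES2 signs are random under
    permutation); averaging 25 splits washes them out at equal width."""
    ds = sg.simulate_dataset(100, random_state=8)
    gs = collection["b"]
    _, m1 = sg.null_statistic_matrix(
        ds, gs, sg.StatisticSpec("es-avg"), n_perm=2000, random_state=14
    )
    _, m25 = sg.null_statistic_matrix(
        ds, gs, sg.StatisticSpec("es-avg-multi", n_splits=25),
        n_perm=400, random_state=14,
    )
    sd1, sd25 = m1.std(ddof=1), m25.std(ddof=1)
    assert abs(sd25 - sd1) / sd1 < 0.15
    assert sg.count_histogram_modes(m25[0]) <= sg.count_histogram_modes(m1[0])


def test_enrichment_analysis_end_to_end(small_dataset, collection):
    results = sg.enrichment_analysis(
        small_dataset,
        collection,
        spec=sg.StatisticSpec("es"),
        n_perm=300,
        random_state=6,
        keep_null=True,
    )
    by_name = {r.gene_set: r for r in results}
    assert set(by_name) == set("abcdefghijklmnopqrstu")
    assert by_name["b"].p.value < 0.05  # strong association detected
    assert by_name["b"].null.n_perm == 300
    for r in results:
        assert -1.0 <= r.observed <= 1.0
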