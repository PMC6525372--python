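"""Stratified splitting and the split-averaged statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import splitgsea as sg

from conftest import random_small_dataset


def test_split_two_per_class_is_forced():
    ids = ["a1", "a2", "b1", "b2"]
    labels = ["A", "A", "B", "B"]
    s1, s2 = sg.stratified_split(ids, labels, random_state=0)
    for half in (s1, s2):
        assert len(half) == 2
        assert len({"a1", "a2"} & set(half)) == 1
        assert len({"b1", "b2"} & set(half)) == 1


def test_split_294_cohort_gives_equal_halves():
    ids = [f"s{i}" for i in range(294)]
    labels = ["poor"] * 176 + ["good"] * 118
    s1, s2 = sg.stratified_split(ids, labels, random_state=5)
    assert len(s1) == len(s2) == 147
    assert abs(sum(l == "poor" for l in np.array(labels)[[ids.index(s) for s in s1]]) - 88) <= 1


def test_split_deterministic_given_stream():
    ids = [f"s{i}" for i in range(50)]
    labels = ["A"] * 25 + ["B"] * 25
    first = sg.stratified_split(ids, labels, random_state=123)
    second = sg.stratified_split(ids, labels, random_state=123)
    assert first == second


def test_split_rejects_tiny_class():
    with pytest.raises(sg.DegeneratePhenotypeError):
        sg.stratified_split(["a", "b", "c"], ["A", "B", "B"], random_state=0)


@given(
    n_a=st.integers(2, 15),
    n_b=st.integers(2, 15),
    seed=st.integers(0, 10_000),
)
def test_split_partition_properties(n_a, n_b, seed):
    """Halves are disjoint, cover the cohort, stratified within one sample."""
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    labels = ["A"] * n_a + ["B"] * n_b
    s1, s2 = sg.stratified_split(ids, labels, random_state=seed)
    assert set(s1) | set(s2) == set(ids)
    assert not (set(s1) & set(s2))
    assert abs(len(s1) - len(s2)) <= 1
    for prefix, count in (("a", n_a), ("b", n_b)):
        in_s1 = sum(1 for s in s1 if s.startswith(prefix))
        assert abs(in_s1 - (count - in_s1)) <= 1


def test_es_avg_is_mean_of_two_core_scores(small_dataset, collection):
    gs = collection["b"]
    s1, s2 = sg.stratified_split(
        small_dataset.sample_ids, small_dataset.phenotype, random_state=2
    )
    value = sg.es_avg(small_dataset, gs, split=(s1, s2))
    expected = []
    for half in (s1, s2):
        sub = small_dataset.subset_samples(np.array(half))
        es, _ = sg.enrichment_score(sg.rank_genes(sub), gs, dataset=sub)
        expected.append(es)
    assert value == pytest.approx(0.5 * sum(expected), abs=1e-12)
    assert -1.0 <= value <= 1.0


def test_es_avg_multi_with_one_split_equals_es_avg(small_dataset, collection):
    gs = collection["c"]
    assert sg.es_avg_multi(small_dataset, gs, 1, random_state=77) == pytest.approx(
        sg.es_avg(small_dataset, gs, random_state=77), abs=1e-15
    )


def test_split_scheme_reuse_and_validation(small_dataset, collection):
    scheme = sg.SplitScheme.draw(small_dataset, 3, random_state=5)
    assert len(scheme) == 3
    # identical splits give identical statistics across calls
    a = sg.es_avg_multi(small_dataset, collection["b"], 3, scheme=scheme)
    b = sg.es_avg_multi(small_dataset, collection["b"], 3, scheme=scheme)
    assert a == b
    with pytest.raises(ValueError, match="overlap"):
        sg.SplitScheme(splits=[(("s1", "s2"), ("s2", "s3"))])
    with pytest.raises(ValueError, match="n_splits"):
        sg.es_avg_multi(small_dataset, collection["b"], 2, scheme=scheme)


def test_statistic_spec_validation():
    with pytest.raises(ValueError):
        sg.StatisticSpec("nope")
    with pytest.raises(ValueError):
        sg.StatisticSpec("es-avg-multi", n_splits=0)
    assert sg.StatisticSpec("es").effective_splits == 0
    assert sg.StatisticSpec("es-avg").effective_splits == 1


def test_split_statistic_antisymmetry():
    """Swapping phenotype classes negates ES_avg when halves are tie-free."""
    rng = np.random.default_rng(21)
    checked = 0
    for trial in range(50):
        ds = random_small_dataset(rng, n_genes=4, n_per_class=10)
        gs = sg.GeneSet("s", [f"g{i}" for i in range(2)])
        s1, s2 = sg.stratified_split(ds.sample_ids, ds.phenotype, random_state=trial)
        halves = [ds.subset_samples(np.array(h)) for h in (s1, s2)]

        def unambiguous(half):
            # needs tie-free r and a unique extremum magnitude: when the
            # running sum's max and min magnitudes coincide the sign of ES
            # is a convention, not a property of the data
            ranking = sg.rank_genes(half)
            if len(np.unique(ranking.correlations)) != ds.n_genes:
                return False
            _, profile = sg.enrichment_score(ranking, gs, dataset=half)
            return abs(profile.values.max() + profile.values.min()) > 1e-9

        if not all(unambiguous(h) for h in halves):
            continue
        fwd = sg.es_avg(ds, gs, split=(s1, s2))
        rev = sg.es_avg(ds.swap_classes(), gs, split=(s1, s2))
        assert rev == pytest.approx(-fwd, abs=1e-12)
        checked += 1
    assert checked >= 5


def test_split_sampling_distribution_narrows_with_m(small_dataset, collection):
    """Split-choice spread of <ES_avg> shrinks as splits are averaged."""
    gs = collection["k"]
    sd = {}
    for m in (1, 25):
        draws = sg.split_sampling_distribution(
            small_dataset, gs, n_splits=m, n_draws=300, random_state=4
        )
        assert np.all(np.abs(draws) <= 1.0)
        sd[m] = draws.std(ddof=1)
    assert sd[25] < sd[1]
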