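"""Rank correlation and running-sum enrichment score."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import splitgsea as sg
from splitgsea.core import CorrelationRanking

from _oracles import brute_enrichment_score, brute_scaled_mann_whitney
from conftest import random_small_dataset


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([3, 4], [1, 2], 1.0),               # complete separation
        ([1, 4], [2, 3], 0.0),               # U = half of n_a * n_b
        ([1, 2, 4], [3, 5, 6], 2 / 9 - 1),   # U = 1 by pair counting
        ([1, 1], [1, 1], 0.0),               # all ties count one half
    ],
)
def test_scaled_mann_whitney_examples(a, b, expected):
    assert sg.scaled_mann_whitney(a, b) == pytest.approx(expected, abs=1e-12)


@given(
    a=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    b=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
)
def test_scaled_mann_whitney_matches_pair_counting(a, b):
    """Integer inputs force ties, exercising the mid-rank convention."""
    assert sg.scaled_mann_whitney(a, b) == pytest.approx(
        brute_scaled_mann_whitney(a, b), abs=1e-12
    )


def test_scaled_mann_whitney_rejects_empty_group():
    with pytest.raises(sg.DegeneratePhenotypeError):
        sg.scaled_mann_whitney([], [1.0])


def test_rank_genes_single_gene_direction():
    ds = sg.ExpressionDataset(
        gene_ids=["g"],
        values=[[2.0, 2.5, 1.0, 0.5]],
        sample_ids=list("wxyz"),
        phenotype=np.array(["A", "A", "B", "B"]),
    )
    ranking = sg.rank_genes(ds)
    assert ranking.correlations[0] == 1.0
    assert list(ranking.ordering) == [0]


def test_rank_genes_label_swap_negates_and_reverses():
    rng = np.random.default_rng(7)
    ds = random_small_dataset(rng, n_genes=15, n_per_class=5)
    fwd = sg.rank_genes(ds)
    rev = sg.rank_genes(ds.swap_classes())
    np.testing.assert_allclose(rev.correlations, -fwd.correlations, atol=1e-12)
    if len(np.unique(fwd.correlations)) == ds.n_genes:  # tie-free
        assert list(rev.ordering) == list(fwd.ordering[::-1])


def test_rank_genes_positive_block_effect(catalogue):
    """Genes with a positive mean shift correlate positively on average."""
    rng = np.random.default_rng(3)
    means = []
    for _ in range(100):
        ds = sg.simulate_dataset(25, rng, catalogue=catalogue)
        r = sg.rank_genes(ds).correlations
        means.append(r[420:440].mean())  # block ii, dmu = 0.5
    assert np.mean(means) > 0.1


@pytest.mark.parametrize(
    "members, expected_es, expected_running",
    [
        ([0, 1], 1.0, [0.8 / 1.3, 1.0, 0.5, 0.0]),
        ([1, 3], -0.61538461538461537, [-0.5, -0.5 + 0.5 / 1.3, -0.61538461538461537, 0.0]),
    ],
)
def test_enrichment_score_hand_examples(members, expected_es, expected_running):
    ranking = CorrelationRanking(
        correlations=np.array([0.8, 0.5, -0.5, -0.8]), ordering=np.arange(4)
    )
    es, profile = sg.enrichment_score(ranking, members)
    assert es == pytest.approx(expected_es, abs=1e-12)
    np.testing.assert_allclose(profile.values, expected_running, atol=1e-12)
    assert profile.hit_normalization == pytest.approx(1.3)


def test_enrichment_score_errors():
    ranking = CorrelationRanking(np.array([0.0, 0.0, 0.5]), np.array([2, 0, 1]))
    with pytest.raises(ValueError, match="N_R = 0"):
        sg.enrichment_score(ranking, [0, 1])
    with pytest.raises(ValueError, match="proper subset"):
        sg.enrichment_score(ranking, [0, 1, 2])
    gs = sg.GeneSet("absent", ["nope"])
    ds = sg.ExpressionDataset(
        gene_ids=["g0", "g1"],
        values=[[1.0, 2.0, 0.5, 0.1], [0.2, 0.3, 0.9, 1.1]],
        sample_ids=list("abcd"),
        phenotype=np.array(["A", "A", "B", "B"]),
    )
    with pytest.raises(ValueError, match="absent"):
        sg.enrichment_score(sg.rank_genes(ds), gs, dataset=ds)


def test_enrichment_score_invariants_random():
    """|ES| <= 1 and the running sum closes at zero on random instances."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        ds = random_small_dataset(rng)
        ranking = sg.rank_genes(ds)
        k = int(rng.integers(1, ds.n_genes))
        members = rng.choice(ds.n_genes, size=k, replace=False)
        if np.all(ranking.correlations[members] == 0):
            continue
        es, profile = sg.enrichment_score(ranking, members)
        assert abs(es) <= 1.0 + 1e-12
        assert abs(profile.values[-1]) < 1e-9
        assert len(profile) == ds.n_genes


def test_top_k_positive_set_reaches_unity():
    """A set that is exactly the top-k genes, all r > 0, attains ES = 1."""
    r = np.array([0.9, 0.7, 0.4, -0.2, -0.8])
    ranking = CorrelationRanking(r, np.argsort(-r, kind="stable"))
    es, profile = sg.enrichment_score(ranking, [0, 1, 2])
    assert es == pytest.approx(1.0, abs=1e-12)
    assert profile.values[2] == pytest.approx(1.0, abs=1e-12)


def test_enrichment_score_matches_gseapy_prerank():
    """Cross-check the running-sum ES against an independent implementation."""
    gseapy = pytest.importorskip("gseapy")
    import pandas as pd

    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(80)]
    r = np.sort(rng.normal(size=80))[::-1]
    members = [genes[i] for i in [1, 4, 11, 30, 55, 70]]
    res = gseapy.prerank(
        rnk=pd.Series(r, index=genes),
        gene_sets={"S": members},
        permutation_num=0,
        weight=1.0,
        min_size=1,
        max_size=100,
        outdir=None,
        no_plot=True,
        seed=0,
    )
    ranking = CorrelationRanking(r, np.arange(80))
    es, _ = sg.enrichment_score(ranking, [1, 4, 11, 30, 55, 70])
    assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-6)


def test_enrichment_score_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    for _ in range(40):
        ds = random_small_dataset(rng)
        ranking = sg.rank_genes(ds)
        k = int(rng.integers(1, ds.n_genes))
        members = rng.choice(ds.n_genes, size=k, replace=False)
        if np.all(ranking.correlations[members] == 0):
            continue
        es, profile = sg.enrichment_score(ranking, members)
        es_ref, running_ref = brute_enrichment_score(
            ranking.correlations, ranking.ordering, members
        )
        assert es == pytest.approx(es_ref, abs=1e-12)
        np.testing.assert_allclose(profile.values, running_ref, atol=1e-12)
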