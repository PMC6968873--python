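"""Temporal core-periphery: consistency, template, annealing, nulls."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

import spontnet as sn
from spontnet.multilayer import FlexibilityProfile, MultilayerNetwork
from _oracles import (
    brute_core_quality,
    exhaustive_max_core_quality,
    random_graph,
)


def random_G(rng, n):
    G = rng.random((n, n))
    G = np.triu(G, 1)
    return G + G.T


# ---------------------------------------------------------------------------
# consistency matrix
# ---------------------------------------------------------------------------

def test_consistency_counts_layer_fractions():
    n = 4
    layers = [np.zeros((n, n)) for _ in range(5)]
    for u in (0, 2, 4):  # edge (0,1) in 3 of 5 layers
        layers[u][0, 1] = layers[u][1, 0] = 1
    for u in range(5):  # edge (2,3) in every layer
        layers[u][2, 3] = layers[u][3, 2] = 1
    ml = MultilayerNetwork(
        node_ids=np.arange(n), layers=layers, day_offsets=list(range(5))
    )
    cm = sn.consistency_matrix(ml)
    assert cm.G[0, 1] == pytest.approx(0.6)
    assert cm.G[2, 3] == pytest.approx(1.0)
    assert cm.G[0, 3] == 0.0
    assert (np.diag(cm.G) == 0).all()
    assert cm.T == 5


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def test_template_closed_form_identities():
    # maximally fuzzy: every entry is exactly 0.5
    np.testing.assert_allclose(sn.core_template(10, 0.0, 0.5), 0.5)
    # the pivot entry m = beta*N is 0.5 for any alpha < 1
    for alpha in (0.1, 0.5, 0.9):
        c = sn.core_template(10, alpha, 0.5)  # pivot at m = 5
        assert c[4] == pytest.approx(0.5)


def test_template_nondecreasing_everywhere():
    for alpha in np.linspace(0, 1, 6):
        for beta in np.linspace(0, 1, 6):
            c = sn.core_template(25, alpha, beta)
            assert np.all(np.diff(c) >= 0)
            assert np.all((c >= 0) & (c <= 1))


def test_template_step_limit_at_alpha_one():
    c = sn.core_template(10, 1.0, 0.5)
    np.testing.assert_array_equal(c[:4], 0.0)
    assert c[4] == 0.5  # m = beta*N exactly
    np.testing.assert_array_equal(c[5:], 1.0)


# ---------------------------------------------------------------------------
# core quality
# ---------------------------------------------------------------------------

def test_core_quality_zero_matrix_and_brute_force():
    rng = np.random.default_rng(0)
    c = rng.random(4)
    assert sn.core_quality(np.zeros((4, 4)), c) == 0.0
    G = random_G(rng, 4)
    assert sn.core_quality(G, c) == pytest.approx(brute_core_quality(G, c))


def test_swapping_identical_rows_leaves_quality_unchanged():
    G = np.array(
        [
            [0.0, 0.5, 0.2, 0.2],
            [0.5, 0.0, 0.2, 0.2],
            [0.2, 0.2, 0.0, 0.9],
            [0.2, 0.2, 0.9, 0.0],
        ]
    )
    c = np.array([0.9, 0.1, 0.5, 0.7])
    swapped = c.copy()
    swapped[[0, 1]] = swapped[[1, 0]]  # nodes 0 and 1 are structurally identical
    assert sn.core_quality(G, c) == pytest.approx(sn.core_quality(G, swapped))


def test_quality_invariant_under_simultaneous_permutation():
    rng = np.random.default_rng(1)
    G = random_G(rng, 8)
    c = rng.random(8)
    perm = rng.permutation(8)
    assert sn.core_quality(G, c) == pytest.approx(
        sn.core_quality(G[np.ix_(perm, perm)], c[perm])
    )


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------

def test_annealed_quality_matches_factorial_oracle():
    rng = np.random.default_rng(2)
    for trial in range(10):
        n = int(rng.integers(5, 8))
        G = random_G(rng, n)
        alpha, beta = rng.uniform(0.1, 0.9), rng.uniform(0.2, 0.9)
        res = sn.anneal_coreness(
            G, alpha, beta, rng=rng, n_restarts=5,
            sweep_size=200, stall_sweeps=20, max_sweeps=300,
        )
        assert res.R == pytest.approx(
            exhaustive_max_core_quality(G, sn.core_template(n, alpha, beta))
        )
    assert sorted(res.coreness.tolist()) == pytest.approx(
        sorted(sn.core_template(n, alpha, beta).tolist())
    )


def test_default_restart_count_is_ten():
    import inspect

    assert inspect.signature(sn.anneal_coreness).parameters["n_restarts"].default == 10


def test_persistent_edge_between_core_nodes_never_hurts_optimal_quality():
    rng = np.random.default_rng(3)
    n = 7
    tmpl = sn.core_template(n, 0.6, 0.6)
    for _ in range(5):
        G = random_G(rng, n)
        base = exhaustive_max_core_quality(G, tmpl)
        res = sn.anneal_coreness(G, 0.6, 0.6, rng=rng, n_restarts=5,
                                 sweep_size=150, stall_sweeps=20)
        top2 = np.argsort(-res.coreness)[:2]
        G2 = G.copy()
        G2[top2[0], top2[1]] = G2[top2[1], top2[0]] = 1.0
        assert exhaustive_max_core_quality(G2, tmpl) >= base - 1e-12


def test_constant_template_flags_arbitrary_core_selection():
    rng = np.random.default_rng(4)
    res = sn.anneal_coreness(random_G(rng, 10), 0.0, 0.5, rng=rng,
                             n_restarts=2, sweep_size=50, stall_sweeps=5)
    with pytest.warns(UserWarning, match="tie-break"):
        mask = res.core_mask("top10")
    assert mask.sum() == 1
    # midpoint and top rules partition the node set
    mid = res.core_mask("midpoint")
    assert set(np.flatnonzero(mid)) | set(np.flatnonzero(~mid)) == set(range(10))


# ---------------------------------------------------------------------------
# permutation null and grid
# ---------------------------------------------------------------------------

def test_shuffled_null_preserves_weight_multiset():
    rng = np.random.default_rng(5)
    G = random_G(rng, 12)
    Gn = sn.shuffled_consistency(G, rng)
    iu = np.triu_indices(12, 1)
    assert sorted(G[iu]) == pytest.approx(sorted(Gn[iu]))
    np.testing.assert_array_equal(Gn, Gn.T)
    assert (np.diag(Gn) == 0).all()
    assert not np.allclose(G, Gn)


def test_relabel_null_preserves_optimal_quality_exactly():
    """Row/column relabeling cannot change the best achievable R (the
    objective is permutation-invariant), which is why the entry-shuffle
    null is the default."""
    rng = np.random.default_rng(6)
    G = random_G(rng, 6)
    tmpl = sn.core_template(6, 0.5, 0.5)
    Gr = sn.shuffled_consistency(G, rng, method="relabel")
    assert exhaustive_max_core_quality(Gr, tmpl) == pytest.approx(
        exhaustive_max_core_quality(G, tmpl)
    )


def test_grid_mean_delta_near_zero_for_structureless_matrix():
    rng = np.random.default_rng(7)
    deltas = []
    for _ in range(3):
        G = random_G(rng, 10)
        grid = sn.grid_search(
            G, rng=rng, grid_size=5, n_null=10,
            n_restarts=1, sweep_size=100, stall_sweeps=5, max_sweeps=50,
        )
        deltas.append(grid.table["delta_R"].mean())
    se = np.std(deltas) / np.sqrt(len(deltas)) + 1e-9
    assert abs(np.mean(deltas)) < max(3 * se, 0.5)


# ---------------------------------------------------------------------------
# flexibility vs coreness
# ---------------------------------------------------------------------------

def make_profile(ids, rank_mean):
    return FlexibilityProfile(
        node_ids=np.asarray(ids),
        mean_flexibility=np.asarray(rank_mean, dtype=float) / max(rank_mean),
        rank_mean=np.asarray(rank_mean, dtype=float),
        n_samples=10,
        gamma_range=(0.5, 1.5),
        omega_range=(0.1, 1.0),
    )


def make_coreness(ids, coreness):
    return sn.CorenessResult(
        node_ids=np.asarray(ids),
        coreness=np.asarray(coreness, dtype=float),
        alpha=0.5,
        beta=0.5,
        R=1.0,
    )


def test_exact_inverse_relation_gives_rho_minus_one():
    ids = np.arange(20)
    flex = np.arange(1, 21, dtype=float)
    prof = make_profile(ids, flex)
    core = make_coreness(ids, 1 - flex / flex.max())
    rho, _ = sn.flexibility_vs_coreness(prof, core)
    assert rho == pytest.approx(-1.0)


def test_independent_vectors_give_rho_near_zero():
    rng = np.random.default_rng(8)
    rhos = []
    for _ in range(30):
        ids = np.arange(40)
        prof = make_profile(ids, rng.permutation(40) + 1.0)
        core = make_coreness(ids, rng.random(40))
        rhos.append(sn.flexibility_vs_coreness(prof, core)[0])
    se = np.std(rhos) / np.sqrt(len(rhos))
    assert abs(np.mean(rhos)) < 3 * se


def test_constant_coreness_flagged_as_undefined():
    ids = np.arange(10)
    prof = make_profile(ids, np.arange(1, 11, dtype=float))
    core = make_coreness(ids, np.full(10, 0.5))
    with pytest.warns(UserWarning, match="constant"):
        rho, p = sn.flexibility_vs_coreness(prof, core)
    assert np.isnan(rho)
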