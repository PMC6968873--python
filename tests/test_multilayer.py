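"""Multilayer modularity, flexibility, and parameter-space bounding."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import spontnet as sn
from spontnet.multilayer import MultilayerNetwork, supra_modularity_matrix
from _oracles import (
    brute_multilayer_modularity,
    exhaustive_max_quality,
    random_graph,
)


def planted_layers(rng, labels_per_layer, p_in=0.9, p_out=0.05):
    layers = []
    for labels in labels_per_layer:
        n = len(labels)
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = p_in if labels[i] == labels[j] else p_out
                if rng.random() < p:
                    A[i, j] = A[j, i] = 1
        layers.append(A)
    return layers


def make_ml(layers):
    return MultilayerNetwork(
        node_ids=np.arange(layers[0].shape[0]),
        layers=layers,
        day_offsets=list(range(len(layers))),
    )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def test_intersection_node_set():
    cfg = sn.SyntheticConfig(
        n_cells=50,
        n_sessions=3,
        day_offsets=(0, 2, 5),
        n_frames=400,
        dropout_prob=0.2,
        seed=0,
    )
    sessions, _ = sn.generate_study(cfg)
    nets = [sn.build_network(s, n_jitter=100, rng=1) for s in sessions]
    ml = sn.build_multilayer(nets)
    expected = set(sessions[0].cell_ids)
    for s in sessions[1:]:
        expected &= set(s.cell_ids)
    assert set(ml.node_ids.tolist()) == expected
    assert ml.n_layers == 3


def test_identical_and_nested_cell_sets():
    rng = np.random.default_rng(0)
    A = random_graph(rng, 6, 0.5)
    full = sn.CorrelationNetwork(
        cell_ids=np.arange(6), W=A, R_raw=A, P=A, A=A, n_jitter=100,
        session_id="a", day_offset=0,
    )
    sub = sn.CorrelationNetwork(
        cell_ids=np.arange(4), W=A[:4, :4], R_raw=A[:4, :4], P=A[:4, :4],
        A=A[:4, :4], n_jitter=100, session_id="b", day_offset=1,
    )
    assert sn.build_multilayer([full, full]).n_nodes == 6
    assert sn.build_multilayer([full, sub]).n_nodes == 4


# ---------------------------------------------------------------------------
# multilayer modularity value
# ---------------------------------------------------------------------------

def test_zero_coupling_equals_sum_of_single_layer_modularities():
    rng = np.random.default_rng(1)
    layers = [random_graph(rng, 8, 0.4) for _ in range(3)]
    ml = make_ml(layers)
    labels = rng.integers(0, 3, size=(8, 3))
    q = sn.multilayer_modularity(ml, labels, gamma=1.2, omega=0.0)
    q_sum = sum(
        sn.modularity(L, labels[:, u], 1.2) for u, L in enumerate(layers)
    )
    assert q == pytest.approx(q_sum)


def test_constant_labels_coupling_contribution():
    rng = np.random.default_rng(2)
    layers = [random_graph(rng, 6, 0.5) for _ in range(4)]
    ml = make_ml(layers)
    labels = np.tile(rng.integers(0, 2, size=6)[:, None], (1, 4))
    omega = 0.7
    q0 = sn.multilayer_modularity(ml, labels, 1.0, 0.0)
    q = sn.multilayer_modularity(ml, labels, 1.0, omega)
    # ordered adjacent-layer pairs: 2 * omega * N * (T - 1)
    assert q - q0 == pytest.approx(2 * omega * 6 * 3)


def test_multilayer_matches_brute_force_quadruple_loop():
    rng = np.random.default_rng(3)
    for _ in range(4):
        layers = [random_graph(rng, 4, 0.6) for _ in range(2)]
        ml = make_ml(layers)
        labels = rng.integers(0, 2, size=(4, 2))
        g, w = rng.uniform(0.3, 1.5), rng.uniform(0.1, 1.0)
        assert sn.multilayer_modularity(ml, labels, g, w) == pytest.approx(
            brute_multilayer_modularity(layers, labels, g, w)
        )


# ---------------------------------------------------------------------------
# maximization
# ---------------------------------------------------------------------------

def test_supra_maximizer_matches_exhaustive_search():
    rng = np.random.default_rng(4)
    for _ in range(3):
        layers = [random_graph(rng, 5, 0.5) for _ in range(2)]
        for L in layers:
            if L.sum() == 0:
                L[0, 1] = L[1, 0] = 1
        ml = make_ml(layers)
        g, w = rng.uniform(0.5, 1.5), rng.uniform(0.1, 1.0)
        part = sn.maximize_multilayer(ml, g, w, rng=rng, n_runs=20)
        qx = exhaustive_max_quality(supra_modularity_matrix(ml, g, w))
        assert part.Q_value == pytest.approx(qx)


def test_large_coupling_freezes_labels_across_layers():
    rng = np.random.default_rng(5)
    labels_per_layer = [np.repeat([0, 1], 6), np.repeat([1, 0], 6), rng.permutation(np.repeat([0, 1], 6))]
    ml = make_ml(planted_layers(rng, labels_per_layer))
    part = sn.maximize_multilayer(ml, gamma=1.0, omega=100.0, rng=rng, n_runs=5)
    f = sn.flexibility(part.labels)
    np.testing.assert_array_equal(f, np.zeros(12))


def test_zero_coupling_decouples_layers():
    rng = np.random.default_rng(6)
    lab1 = np.repeat([0, 1], 8)
    lab2 = np.array([0, 1] * 8)
    ml = make_ml(planted_layers(rng, [lab1, lab2]))
    part = sn.maximize_multilayer(ml, gamma=1.0, omega=0.0, rng=rng, n_runs=10)
    for u, truth in enumerate((lab1, lab2)):
        single = sn.maximize_modularity(ml.layers[u], 1.0, rng=rng, n_runs=10)
        assert adjusted_rand_score(part.labels[:, u], single) >= 0.9
        assert adjusted_rand_score(part.labels[:, u], truth) >= 0.9


# ---------------------------------------------------------------------------
# flexibility
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "labels, expected",
    [
        (np.array([[1, 1, 1, 1, 1]]), 0.0),
        (np.array([[0, 1, 0, 1, 0]]), 1.0),
        (np.array([[0, 0, 1, 1, 2]]), 0.5),
    ],
)
def test_flexibility_counts_label_changes(labels, expected):
    assert sn.flexibility(labels)[0] == pytest.approx(expected)


def test_mean_flexibility_nonincreasing_in_coupling():
    """Stronger inter-layer coupling makes communities more persistent
    (monotone on average over seeds)."""
    omegas = [0.05, 0.5, 3.0]
    means = np.zeros(len(omegas))
    for seed in range(20):
        rng = np.random.default_rng(seed)
        labels_per_layer = [
            rng.permutation(np.repeat([0, 1, 2], 4)) for _ in range(3)
        ]
        ml = make_ml(planted_layers(rng, labels_per_layer))
        for k, w in enumerate(omegas):
            part = sn.maximize_multilayer(ml, 1.0, w, rng=rng, n_runs=3)
            means[k] += sn.flexibility(part.labels).mean()
    means /= 20
    assert means[0] >= means[1] >= means[2]


# ---------------------------------------------------------------------------
# parameter bounds and sampling
# ---------------------------------------------------------------------------

def test_feasible_box_nonempty_and_corners_valid(core_runs):
    (g_lo, g_hi), (w_lo, w_hi) = core_runs[0]["bounds"]
    assert g_lo < g_hi
    assert w_lo < w_hi


def test_bounds_error_when_no_feasible_region():
    # layers with no edges at all cannot support non-trivial structure
    empty = [np.zeros((4, 4)) for _ in range(2)]
    ml = make_ml(empty)
    with pytest.raises(RuntimeError, match="no feasible"):
        sn.estimate_parameter_bounds(
            ml, rng=0, gamma_limits=(0.5, 2.0), omega_limits=(0.0, 1.0),
            grid_points=3, n_runs=1,
        )


def test_sampled_profile_shapes_and_ranges():
    rng = np.random.default_rng(7)
    labels_per_layer = [np.repeat([0, 1, 2], 5) for _ in range(3)]
    ml = make_ml(planted_layers(rng, labels_per_layer))
    prof = sn.sample_flexibility(
        ml, n_samples=20, rng=rng, bounds=((0.8, 1.2), (0.05, 0.5))
    )
    assert prof.mean_flexibility.shape == (15,)
    assert np.all((prof.mean_flexibility >= 0) & (prof.mean_flexibility <= 1))
    assert np.all((prof.rank_mean >= 1) & (prof.rank_mean <= 15))
    assert prof.n_samples == 20
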