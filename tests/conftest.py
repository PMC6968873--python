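"""Shared fixtures: synthetic study conditions and cached pipeline runs.

The two study designs used throughout the recovery tests:

* ``hierarchy study`` — one session, 64 cells, a 2x2 nested module
  hierarchy with signal weights (0.9, 0.9) and noise 0.8 so that the
  jitter-thresholded graph shows a density gradient (within-fine ~0.95,
  within-coarse-only ~0.45, between ~0.05) instead of saturating.
* ``core study`` — five sessions over 14 days, 100 cells in five flat
  modules, a 20% persistent core assembly, heterogeneous drift averaging
  0.25/day so that most periphery cells reorganize at least once.

Expensive multi-seed analyses are computed once per test session and shared
between the unit and acceptance tests.
"""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

import spontnet as sn

HIERARCHY_SEEDS = list(range(20))
CORE_SEEDS = list(range(10))


def hierarchy_config(seed):
    return sn.SyntheticConfig(
        n_cells=64,
        n_sessions=1,
        day_offsets=(0,),
        n_frames=1500,
        hierarchy_branching=(2, 2),
        signal_strength_per_level=(0.9, 0.9),
        noise_sd=0.8,
        dropout_prob=0.0,
        seed=seed,
    )


def core_config(seed):
    return sn.SyntheticConfig(
        n_cells=100,
        n_sessions=5,
        day_offsets=(0, 3, 7, 10, 14),
        n_frames=1500,
        hierarchy_branching=(5,),
        signal_strength_per_level=(1.0,),
        noise_sd=0.8,
        dropout_prob=0.05,
        drift_prob_per_day=0.25,
        core_fraction=0.2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def hierarchy_runs():
    """Hierarchical sweep on 20 planted 2-level studies."""
    out = []
    for seed in HIERARCHY_SEEDS:
        sessions, truth = sn.generate_study(hierarchy_config(seed))
        net = sn.build_network(sessions[0], n_jitter=150, rng=seed)
        hp = sn.hierarchical_sweep(net.A, rng=seed + 1000, n_runs=10, n_null=100)
        ari = []
        for lvl in (1, 2):
            if hp.n_levels >= lvl:
                ari.append(
                    adjusted_rand_score(
                        truth.level_labels(0, lvl), hp.level_labels(lvl)
                    )
                )
            else:
                ari.append(0.0)
        out.append(
            {
                "seed": seed,
                "n_levels": hp.n_levels,
                "significance": list(hp.significance),
                "ari1": ari[0],
                "ari2": ari[1],
                "positions": sessions[0].positions,
                "partition": hp,
            }
        )
    return out


@pytest.fixture(scope="session")
def core_runs():
    """Full multilayer + core-periphery analysis on 10 stable-core studies."""
    out = []
    for seed in CORE_SEEDS:
        sessions, truth = sn.generate_study(core_config(seed))
        rng = np.random.default_rng(10_000 + seed)
        nets = [sn.build_network(s, n_jitter=120, rng=rng) for s in sessions]
        ml = sn.build_multilayer(nets)
        cm = sn.consistency_matrix(ml)
        core_in_ml = truth.core_mask[ml.node_ids]

        res = sn.anneal_coreness(
            cm, 0.5, 0.8, rng=rng, n_restarts=4,
            sweep_size=1000, stall_sweeps=15, max_sweeps=500,
        )
        top = res.core_mask("top20")
        overlap = (top & core_in_ml).sum() / min(top.sum(), core_in_ml.sum())

        bounds = sn.estimate_parameter_bounds(
            ml, rng=rng, gamma_limits=(0.3, 3.0), omega_limits=(0.0, 2.0)
        )
        prof = sn.sample_flexibility(ml, n_samples=100, rng=rng, bounds=bounds)
        flex_p = mannwhitneyu(
            prof.rank_mean[core_in_ml],
            prof.rank_mean[~core_in_ml],
            alternative="less",
        ).pvalue
        rho, _ = sn.flexibility_vs_coreness(prof, res)

        mats = sn.session_matrices_from_networks(nets)
        pairs = sn.pairwise_similarity(mats, n_perm=500, rng=rng)
        decay_r, _ = sn.decay_analysis(pairs)
        core_r, noncore_r, _ = sn.core_noncore_stability(
            nets, res, n_perm=500, rng=rng, rule="top20"
        )
        out.append(
            {
                "seed": seed,
                "overlap": overlap,
                "flex_p": flex_p,
                "rho": rho,
                "decay_r": decay_r,
                "core_r": core_r,
                "noncore_r": noncore_r,
                "bounds": bounds,
                "n_nodes": ml.n_nodes,
            }
        )
    return out


@pytest.fixture(scope="session")
def zero_drift_decay():
    """Decay correlations on 5 studies with no drift and no dropout."""
    rs = []
    for seed in range(5):
        cfg = core_config(seed).replace(
            n_cells=60, drift_prob_per_day=0.0, dropout_prob=0.0
        )
        sessions, _ = sn.generate_study(cfg)
        rng = np.random.default_rng(20_000 + seed)
        nets = [sn.build_network(s, n_jitter=120, rng=rng) for s in sessions]
        mats = sn.session_matrices_from_networks(nets)
        pairs = sn.pairwise_similarity(mats, n_perm=500, rng=rng)
        r, _ = sn.decay_analysis(pairs)
        rs.append(r)
    return rs
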