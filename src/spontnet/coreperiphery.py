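"""Temporal core-periphery detection on the cross-session consistency matrix.

The consistency matrix G records, for every cell pair, the fraction of
recording sessions in which the pair's edge was significant.  A *temporal
core* is a set of cells whose mutual connections persist across sessions.
Coreness is modeled with a parametric sigmoidal template

    C*_m = 1 / (1 + exp(-(m - beta*N) * tan(pi*alpha/2))),   m = 1..N,

whose shape parameter alpha in [0, 1] controls the sharpness of the
core-periphery transition (alpha = 0: maximally fuzzy, all 0.5; alpha = 1:
binary step) and beta in [0, 1] controls the core size.  Each node receives
one template value; the assignment (a permutation of the template) is
chosen by simulated annealing to maximize the core quality

    R = sum_ij G_ij C_i C_j.

A grid over (alpha, beta) with a permutation null on G locates parameter
regions where the observed core quality beats chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .multilayer import FlexibilityProfile, MultilayerNetwork
from .reconstruction import CorrelationNetwork
from .similarity import (
    SessionMatrix,
    decay_analysis,
    pairwise_similarity,
    session_matrices_from_networks,
)

logger = logging.getLogger("spontnet")

__all__ = [
    "ConsistencyMatrix",
    "CorenessResult",
    "consistency_matrix",
    "core_template",
    "core_quality",
    "anneal_coreness",
    "shuffled_consistency",
    "grid_search",
    "GridSearchResult",
    "core_noncore_stability",
    "flexibility_vs_coreness",
]


@dataclass
class ConsistencyMatrix:
    """G_ij = fraction of layers in which edge (i, j) was present."""

    G: np.ndarray
    node_ids: np.ndarray
    T: int


@dataclass
class CorenessResult:
    """Annealed coreness assignment at one (alpha, beta)."""

    node_ids: np.ndarray
    coreness: np.ndarray
    alpha: float
    beta: float
    R: float
    null_R: np.ndarray | None = None
    core_threshold_midpoint: float = 0.5

    @property
    def delta_R(self) -> float | None:
        if self.null_R is None or len(self.null_R) == 0:
            return None
        return float(self.R - np.mean(self.null_R))

    def core_mask(self, rule: str = "top10") -> np.ndarray:
        """Binary core membership: 'midpoint' (coreness > 0.5) or 'topXX'
        (top XX% by coreness, ties broken by node order with a warning)."""
        c = self.coreness
        if rule == "midpoint":
            return c > self.core_threshold_midpoint
        if rule.startswith("top"):
            frac = float(rule[3:]) / 100.0
            k = max(1, int(round(frac * len(c))))
            if np.all(c == c[0]):
                warnings.warn(
                    "coreness is constant (degenerate template); top-k core "
                    "selection is an arbitrary tie-break",
                    stacklevel=2,
                )
            order = np.argsort(-c, kind="stable")
            mask = np.zeros(len(c), dtype=bool)
            mask[order[:k]] = True
            return mask
        raise ValueError(f"unknown core rule: {rule}")


# ---------------------------------------------------------------------------
# consistency and template
# ---------------------------------------------------------------------------

def consistency_matrix(ml: MultilayerNetwork) -> ConsistencyMatrix:
    G = np.mean([L for L in ml.layers], axis=0)
    np.fill_diagonal(G, 0.0)
    return ConsistencyMatrix(G=G, node_ids=ml.node_ids, T=ml.n_layers)


def core_template(N: int, alpha: float, beta: float) -> np.ndarray:
    """Sigmoidal coreness template C*_m, m = 1..N, nondecreasing in m.

    alpha = 1 is handled as the binary-step limit (tan(pi/2) diverges):
    0 below beta*N, 1 above, 0.5 at equality.
    """
    if not 0.0 <= alpha <= 1.0 or not 0.0 <= beta <= 1.0:
        raise ValueError("alpha and beta must lie in [0, 1]")
    m = np.arange(1, N + 1, dtype=float)
    pivot = beta * N
    if alpha == 1.0:
        out = np.where(m < pivot, 0.0, np.where(m > pivot, 1.0, 0.5))
        return out.astype(float)
    slope = np.tan(np.pi * alpha / 2.0)
    z = np.clip(-(m - pivot) * slope, -700, 700)
    return 1.0 / (1.0 + np.exp(z))


def core_quality(
    G: np.ndarray, coreness: np.ndarray, normalized: bool = False
) -> float:
    """R = sum_ij G_ij C_i C_j (ordered pairs; zero diagonal of G).

    With ``normalized=True`` the coreness vector is rescaled so that
    sum_ij C_i C_j = 1, making R comparable across (alpha, beta); the
    rescaling is a positive constant at fixed parameters and cannot change
    which permutation is optimal.
    """
    c = np.asarray(coreness, dtype=float)
    if normalized:
        s = c.sum()
        if s > 0:
            c = c / s
    return float(c @ np.asarray(G, dtype=float) @ c)


# ---------------------------------------------------------------------------
# simulated annealing over template permutations
# ---------------------------------------------------------------------------

def _anneal_once(
    G: np.ndarray,
    template: np.ndarray,
    rng: np.random.Generator,
    cooling: float,
    stall_sweeps: int,
    sweep_size: int,
    max_sweeps: int,
    accept_target: float = 0.8,
) -> tuple[np.ndarray, float]:
    n = G.shape[0]
    c = template[rng.permutation(n)]
    S = G @ c
    R = float(c @ S)

    # set the initial temperature so that a typical downhill move accepts
    # with probability ~accept_target
    deltas = []
    for _ in range(min(200, 10 * n)):
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        sa = S[a] - G[a, b] * c[b]
        sb = S[b] - G[a, b] * c[a]
        deltas.append(abs(2.0 * (c[b] - c[a]) * (sa - sb)))
    scale = np.mean(deltas) if deltas else 0.0
    temp = scale / np.log(1.0 / accept_target) if scale > 0 else 1.0

    best_c, best_R = c.copy(), R
    stall = 0
    for _ in range(max_sweeps):
        improved = False
        aa = rng.integers(0, n, size=sweep_size)
        bb = rng.integers(0, n, size=sweep_size)
        uu = rng.random(sweep_size)
        for a, b, u in zip(aa, bb, uu):
            if a == b or c[a] == c[b]:
                continue
            g = G[a, b]
            dR = 2.0 * (c[b] - c[a]) * ((S[a] - g * c[b]) - (S[b] - g * c[a]))
            if dR >= 0 or (temp > 0 and u < np.exp(dR / temp)):
                dc = c[b] - c[a]
                S += G[:, a] * dc - G[:, b] * dc
                c[a], c[b] = c[b], c[a]
                R += dR
                if R > best_R + 1e-12:
                    best_c, best_R = c.copy(), R
                    improved = True
        temp *= cooling
        stall = 0 if improved else stall + 1
        if stall >= stall_sweeps:
            break
    return best_c, best_R


def anneal_coreness(
    G: np.ndarray | ConsistencyMatrix,
    alpha: float,
    beta: float,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 10,
    cooling: float = 0.95,
    stall_sweeps: int = 50,
    sweep_size: int | None = None,
    max_sweeps: int = 1000,
    node_ids: np.ndarray | None = None,
) -> CorenessResult:
    """Best-of-``n_restarts`` annealed assignment of the coreness template.

    The state is a permutation of the template values over nodes; proposals
    swap two nodes' values; cooling is geometric per sweep of ``sweep_size``
    proposals (default N^2); a restart stops after ``stall_sweeps`` sweeps
    without improvement.
    """
    rng = np.random.default_rng(rng)
    if isinstance(G, ConsistencyMatrix):
        if node_ids is None:
            node_ids = G.node_ids
        G = G.G
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    template = core_template(n, alpha, beta)
    if sweep_size is None:
        sweep_size = n * n
    best_c, best_R = None, -np.inf
    for _ in range(max(1, n_restarts)):
        c, R = _anneal_once(
            G, template, rng, cooling, stall_sweeps, sweep_size, max_sweeps
        )
        if R > best_R:
            best_c, best_R = c, R
    if node_ids is None:
        node_ids = np.arange(n)
    return CorenessResult(
        node_ids=np.asarray(node_ids),
        coreness=best_c,
        alpha=alpha,
        beta=beta,
        R=best_R,
    )


# ---------------------------------------------------------------------------
# permutation null and (alpha, beta) grid
# ---------------------------------------------------------------------------

def shuffled_consistency(
    G: np.ndarray, rng: np.random.Generator, method: str = "shuffle"
) -> np.ndarray:
    """Permutation null for G.

    ``"shuffle"`` (default): uniformly permute the off-diagonal entries
    (upper triangle shuffled and mirrored), preserving the weight multiset
    but destroying which pairs are persistent.  ``"relabel"``: apply one
    random permutation symmetrically to rows and columns; note the optimal
    core quality is exactly invariant under relabeling, so this variant can
    only probe annealing noise.
    """
    n = G.shape[0]
    if method == "relabel":
        perm = rng.permutation(n)
        return G[np.ix_(perm, perm)]
    if method != "shuffle":
        raise ValueError(f"unknown null method: {method}")
    iu = np.triu_indices(n, k=1)
    vals = G[iu].copy()
    rng.shuffle(vals)
    out = np.zeros_like(G)
    out[iu] = vals
    return out + out.T


@dataclass
class GridSearchResult:
    """delta_R surface over the (alpha, beta) grid."""

    table: pd.DataFrame          # alpha, beta, R_obs, R_null_mean, delta_R
    alphas: np.ndarray
    betas: np.ndarray
    top_fraction: float

    @property
    def n_points(self) -> int:
        return len(self.table)

    def top_points(self) -> pd.DataFrame:
        k = max(1, int(round(self.top_fraction * len(self.table))))
        return self.table.nlargest(k, "delta_R")


def grid_search(
    G: np.ndarray,
    rng: np.random.Generator | int | None = None,
    grid_size: int = 31,
    n_null: int = 100,
    top_fraction: float = 0.1,
    null_method: str = "shuffle",
    **anneal_kwargs,
) -> GridSearchResult:
    """Observed-minus-null core quality over a (alpha, beta) grid.

    At each of ``grid_size**2`` linearly spaced parameter pairs, R is
    annealed on G and on ``n_null`` permutation surrogates; the surface of
    delta_R = R_obs - mean(R_null) highlights parameter regions where a
    genuine persistent core exists.  The default grid is 31 x 31.
    """
    rng = np.random.default_rng(rng)
    G = np.asarray(G, dtype=float)
    alphas = np.linspace(0.0, 1.0, grid_size)
    betas = np.linspace(0.0, 1.0, grid_size)
    nulls = [shuffled_consistency(G, rng, method=null_method) for _ in range(n_null)]
    rows = []
    for a in alphas:
        for b in betas:
            res = anneal_coreness(G, a, b, rng=rng, **anneal_kwargs)
            null_R = np.array(
                [
                    anneal_coreness(Gn, a, b, rng=rng, **anneal_kwargs).R
                    for Gn in nulls
                ]
            )
            rows.append(
                {
                    "alpha": float(a),
                    "beta": float(b),
                    "R_obs": res.R,
                    "R_null_mean": float(null_R.mean()) if n_null else np.nan,
                    "delta_R": res.R - (float(null_R.mean()) if n_null else 0.0),
                }
            )
    return GridSearchResult(
        table=pd.DataFrame(rows),
        alphas=alphas,
        betas=betas,
        top_fraction=top_fraction,
    )


# ---------------------------------------------------------------------------
# stability analyses
# ---------------------------------------------------------------------------

def core_noncore_stability(
    networks: list[CorrelationNetwork],
    result: CorenessResult,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    rule: str = "top10",
    min_shared: int = 4,
) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Similarity-decay correlations for core vs non-core connections.

    The decay analysis is run twice on shared-cell submatrices of the signed
    weighted networks: once restricted to the core cells (by default the top
    10% ranked by coreness) and once to the remaining cells.  A stable core
    shows a higher (less negative) decay correlation than the periphery.
    """
    rng = np.random.default_rng(rng)
    mask = result.core_mask(rule)
    if mask.sum() < 4:
        warnings.warn(
            f"core group has only {int(mask.sum())} cells; decay estimate "
            "rests on very few edge pairs",
            stacklevel=2,
        )
    core_ids = set(np.asarray(result.node_ids)[mask].tolist())
    noncore_ids = set(np.asarray(result.node_ids)[~mask].tolist())

    out_tables: dict[str, pd.DataFrame] = {}
    rs: list[float] = []
    for name, keep in (("core", core_ids), ("noncore", noncore_ids)):
        mats = []
        for sm in session_matrices_from_networks(networks):
            sel = np.array([c in keep for c in sm.cell_ids])
            mats.append(
                SessionMatrix(
                    session_id=sm.session_id,
                    day_offset=sm.day_offset,
                    cell_ids=sm.cell_ids[sel],
                    M=sm.M[np.ix_(np.flatnonzero(sel), np.flatnonzero(sel))],
                    kind=sm.kind,
                )
            )
        pairs = pairwise_similarity(
            mats, n_perm=n_perm, rng=rng, min_shared=min_shared
        )
        try:
            r, table = decay_analysis(pairs)
        except ValueError:
            warnings.warn(
                f"{name} group: too few usable session pairs for a decay "
                "estimate",
                stacklevel=2,
            )
            r, table = float("nan"), pd.DataFrame()
        rs.append(r)
        out_tables[name] = table
    return rs[0], rs[1], out_tables


def flexibility_vs_coreness(
    flex: FlexibilityProfile, core: CorenessResult
) -> tuple[float, float]:
    """Spearman correlation of rank-averaged flexibility with coreness.

    Flexibility measures variability and coreness stability, so on a
    network with a genuine temporal core the two are inversely related.
    """
    ids_f = np.asarray(flex.node_ids)
    ids_c = np.asarray(core.node_ids)
    shared, i_f, i_c = np.intersect1d(ids_f, ids_c, return_indices=True)
    if shared.size < 3:
        raise ValueError("fewer than 3 shared nodes")
    x = flex.rank_mean[i_f]
    y = core.coreness[i_c]
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(
            "flexibility_vs_coreness undefined: constant input", stacklevel=2
        )
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
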