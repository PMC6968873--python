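"""Single-session community detection and spatial statistics.

Modularity is evaluated exactly as

    Q(gamma) = sum_ij [A_ij - gamma * k_i k_j / 2m] * delta(g_i, g_j)

over all ordered pairs *including* i == j (with A_ii = 0), and without the
conventional 1/2m prefactor.  Positive rescaling does not move the argmax,
and the chosen null-term convention makes the one-module partition score
exactly zero at gamma = 1 — a clean testable identity.

The multi-scale hierarchy is found recursively: split the network at the
coarsest resolution on an ascending gamma grid that produces more than one
module, keep the split only if its modularity beats the 95th percentile of
the same statistic on degree-preserving rewired graphs, then recurse into
each module at equal-or-finer resolutions.  Retained levels therefore all
pass p < 0.05 against the rewiring null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import spearmanr

from ._louvain import maximize_quality, partition_quality

logger = logging.getLogger("spontnet")

__all__ = [
    "HierarchicalPartition",
    "CoAssignmentMatrix",
    "SpatialStats",
    "modularity",
    "modularity_matrix",
    "maximize_modularity",
    "degree_preserving_rewire",
    "hierarchical_sweep",
    "coassignment",
    "spatial_compactness",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalPartition:
    """Nested module labels, coarse (level 1) to fine (level L).

    ``labels`` has shape (n_levels, n_cells); every retained level passed the
    rewiring-null significance test (p < 0.05).  ``splits`` records each
    individual accepted split (parent module, gamma, Q, p).
    """

    labels: np.ndarray
    gamma_per_level: list[float]
    significance: list[float]
    splits: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_levels(self) -> int:
        return self.labels.shape[0]

    @property
    def n_levels_significant(self) -> int:
        return self.n_levels

    @property
    def levels(self) -> list[int]:
        return list(range(1, self.n_levels + 1))

    def level_labels(self, level: int) -> np.ndarray:
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level must be in 1..{self.n_levels}")
        return self.labels[level - 1]


@dataclass
class CoAssignmentMatrix:
    """Fraction of partitions in which each cell pair shares a module."""

    C: np.ndarray
    n_partitions: int


@dataclass
class SpatialStats:
    """Per-module spatial compactness z-scores and their trend over levels.

    ``table`` has one row per scored module: module id, level, size, observed
    mean nearest-same-module-neighbor distance (um), permutation-null mean
    and sd, and the z-score.  ``spearman_rho`` is the study-level Spearman
    correlation of z with hierarchical level.
    """

    table: pd.DataFrame
    spearman_rho: float
    spearman_p: float


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T):
        raise ValueError("A must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("A must have zero diagonal")
    return A


def modularity_matrix(A: np.ndarray, gamma: float) -> np.ndarray:
    """B = A - gamma * k k' / 2m, diagonal included (A_ii = 0)."""
    A = _check_adjacency(A)
    k = A.sum(axis=1)
    twom = k.sum()
    if twom <= 0:
        raise ValueError("empty graph: no edges")
    return A - gamma * np.outer(k, k) / twom


def modularity(A: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Exact evaluation of the (unnormalized) modularity quality function."""
    return partition_quality(modularity_matrix(A, gamma), labels)


def maximize_modularity(
    A: np.ndarray,
    gamma: float = 1.0,
    rng: np.random.Generator | int | None = None,
    n_runs: int = 100,
) -> np.ndarray:
    """Best-of-``n_runs`` greedy Louvain-style maximization of Q(gamma).

    The returned partition's Q is never below that of the all-singletons or
    the one-module partition (both are checked by the engine).  Isolated
    nodes are allowed; graphs without edges are rejected.
    """
    rng = np.random.default_rng(rng)
    B = modularity_matrix(A, gamma)
    labels, _ = maximize_quality(B, rng, n_runs=n_runs)
    return labels


# ---------------------------------------------------------------------------
# hierarchical multi-resolution sweep
# ---------------------------------------------------------------------------

def degree_preserving_rewire(
    A: np.ndarray,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    max_attempts_factor: int = 20,
) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps preserving the degree sequence.

    Repeatedly picks two edges (a, b), (c, d) and rewires them to
    (a, d), (c, b) when that creates neither self-loops nor multi-edges.
    Defaults to ~5m accepted swaps (or the attempt budget, whichever comes
    first), which thoroughly randomizes the graph while keeping degrees.
    Dense graphs may accept fewer swaps; that only makes the null
    conservative.
    """
    A = np.asarray(A)
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    m = len(edges)
    if m < 2:
        return A.copy().astype(float)
    if n_swaps is None:
        n_swaps = 5 * m
    edge_set = set(edges)
    done = 0
    picks = rng.integers(0, m, size=(max_attempts_factor * m, 2))
    coin = rng.random(max_attempts_factor * m)
    for (e1, e2), u in zip(picks, coin):
        if done >= n_swaps:
            break
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if u < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in edge_set or n2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(n1)
        edge_set.add(n2)
        edges[e1] = n1
        edges[e2] = n2
        done += 1
    out = np.zeros_like(A, dtype=float)
    if edge_set:
        ii, jj = np.array(sorted(edge_set)).T
        out[ii, jj] = 1.0
        out[jj, ii] = 1.0
    return out


def _rewired_null_q(
    subA: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    n_null: int,
    n_runs_null: int,
) -> np.ndarray:
    """Max-modularity values on degree-preserving rewirings of ``subA``."""
    out = np.empty(n_null)
    for t in range(n_null):
        An = degree_preserving_rewire(subA, rng)
        _, q = maximize_quality(
            modularity_matrix(An, gamma), rng, n_runs=n_runs_null
        )
        out[t] = q
    return out


def hierarchical_sweep(
    A: np.ndarray,
    rng: np.random.Generator | int | None = None,
    gamma_grid: np.ndarray | None = None,
    n_runs: int = 100,
    n_null: int = 100,
    alpha: float = 0.05,
    min_module_size: int = 4,
    max_levels: int = 12,
    n_runs_null: int = 2,
) -> HierarchicalPartition:
    """Recursive multi-resolution module detection with significance testing.

    At each (sub)network, the coarsest gamma on the ascending grid that
    splits it is found; the split is retained only if its Q exceeds the
    null distribution from ``n_null`` degree-preserving rewirings at
    p < ``alpha``, and recursion continues inside each module.  Levels are
    reported coarse -> fine; a network with no significant split yields a
    partition with zero levels.
    """
    rng = np.random.default_rng(rng)
    A = _check_adjacency(A)
    n = A.shape[0]
    if gamma_grid is None:
        gamma_grid = np.geomspace(0.5, 8.0, 13)
    gamma_grid = np.asarray(gamma_grid, dtype=float)

    paths: list[list[int]] = [[] for _ in range(n)]
    split_rows: list[dict] = []
    next_id = [0]

    def recurse(nodes: np.ndarray, g_start: int, depth: int) -> None:
        if depth > max_levels or nodes.size < max(2, min_module_size):
            return
        subA = A[np.ix_(nodes, nodes)]
        if subA.sum() == 0:
            return
        found = None
        for j in range(g_start, len(gamma_grid)):
            labels, q = maximize_quality(
                modularity_matrix(subA, gamma_grid[j]), rng, n_runs=n_runs
            )
            if labels.max() > 0:
                found = (j, labels, q)
                break
        if found is None:
            return
        j, labels, q_obs = found
        null_q = _rewired_null_q(
            subA, gamma_grid[j], rng, n_null=n_null, n_runs_null=n_runs_null
        )
        p = (1.0 + np.sum(null_q >= q_obs)) / (1.0 + n_null)
        if p >= alpha:
            return
        child_ids = {}
        for c in np.unique(labels):
            child_ids[c] = next_id[0]
            next_id[0] += 1
        for local_i, node in enumerate(nodes):
            paths[node].append(child_ids[labels[local_i]])
        split_rows.append(
            {
                "depth": depth,
                "gamma": float(gamma_grid[j]),
                "n_modules": int(labels.max()) + 1,
                "size": int(nodes.size),
                "Q": float(q_obs),
                "p_value": float(p),
            }
        )
        for c in np.unique(labels):
            recurse(nodes[labels == c], j, depth + 1)

    recurse(np.arange(n), 0, 1)

    n_levels = max((len(p) for p in paths), default=0)
    labels = np.zeros((n_levels, n), dtype=int)
    for i, path in enumerate(paths):
        for lvl in range(n_levels):
            # cells whose recursion stopped early keep their final module
            labels[lvl, i] = path[min(lvl, len(path) - 1)] if path else 0
    splits = pd.DataFrame(split_rows)
    gamma_per_level: list[float] = []
    significance: list[float] = []
    for lvl in range(1, n_levels + 1):
        at = splits[splits["depth"] == lvl]
        gamma_per_level.append(float(at["gamma"].max()) if len(at) else np.nan)
        significance.append(float(at["p_value"].max()) if len(at) else np.nan)
    return HierarchicalPartition(
        labels=labels,
        gamma_per_level=gamma_per_level,
        significance=significance,
        splits=splits,
    )


# ---------------------------------------------------------------------------
# co-assignment consensus
# ---------------------------------------------------------------------------

def coassignment(partitions: list[np.ndarray]) -> CoAssignmentMatrix:
    """C_ij = fraction of partitions in which i and j share a module."""
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    parts = [np.asarray(p) for p in partitions]
    n = parts[0].shape[0]
    if any(p.shape != (n,) for p in parts):
        raise ValueError("partitions must cover the same node set")
    C = np.zeros((n, n))
    for p in parts:
        C += p[:, None] == p[None, :]
    C /= len(parts)
    return CoAssignmentMatrix(C=C, n_partitions=len(parts))


# ---------------------------------------------------------------------------
# spatial compactness
# ---------------------------------------------------------------------------

def _mean_nn_distance(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def spatial_compactness(
    partition: HierarchicalPartition | np.ndarray,
    positions: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> SpatialStats:
    """Nearest-same-module-neighbor z-scores against a position-permutation null.

    For every module (size >= 2) at every level, the observed mean distance
    from each member to its nearest co-member is compared with the same
    statistic after randomly permuting all cells' positions while keeping
    module assignments fixed.  Negative z means more spatially compact than
    chance.  A module containing all cells is permutation-invariant and gets
    z = 0; singleton modules are skipped with a warning.
    """
    rng = np.random.default_rng(rng)
    if isinstance(partition, HierarchicalPartition):
        level_iter = [(lvl, partition.level_labels(lvl)) for lvl in partition.levels]
    else:
        level_iter = [(1, np.asarray(partition))]
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    D = squareform(pdist(positions))

    rows = []
    for lvl, labels in level_iter:
        if labels.shape[0] != n:
            raise ValueError("labels and positions disagree on cell count")
        for mod in np.unique(labels):
            idx = np.flatnonzero(labels == mod)
            if idx.size < 2:
                logger.warning(
                    "spatial_compactness: singleton module %s at level %d skipped",
                    mod,
                    lvl,
                )
                continue
            obs = _mean_nn_distance(D, idx)
            if idx.size == n:
                logger.warning(
                    "spatial_compactness: module %s spans all cells; z = 0", mod
                )
                rows.append(
                    {
                        "module": int(mod),
                        "level": lvl,
                        "size": int(idx.size),
                        "observed": obs,
                        "null_mean": obs,
                        "null_sd": 0.0,
                        "z": 0.0,
                    }
                )
                continue
            null = np.empty(n_perm)
            for t in range(n_perm):
                perm = rng.permutation(n)
                null[t] = _mean_nn_distance(D, perm[idx])
            mu, sd = null.mean(), null.std()
            z = (obs - mu) / sd if sd > 0 else 0.0
            rows.append(
                {
                    "module": int(mod),
                    "level": lvl,
                    "size": int(idx.size),
                    "observed": obs,
                    "null_mean": mu,
                    "null_sd": sd,
                    "z": z,
                }
            )
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["level"].nunique() > 1 and table["z"].nunique() > 1:
        rho, p = spearmanr(table["level"], table["z"])
    else:
        rho, p = np.nan, np.nan
    return SpatialStats(table=table, spearman_rho=float(rho), spearman_p=float(p))
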