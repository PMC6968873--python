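"""Multilayer community dynamics across recording sessions.

The thresholded network of each session becomes one layer of a multilayer
network over the cells present in *every* session.  Multilayer modularity

    Q(gamma, omega) = sum_u sum_ij [A_iju - gamma k_iu k_ju / 2m_u] delta(g_iu, g_ju)
                    + sum_i sum_{|u-v|=1} omega * delta(g_iu, g_iv)

couples each cell to itself in temporally adjacent layers with strength
omega, so one shared label namespace spans all sessions and module
formation/dissolution can be tracked.  Node flexibility is the fraction of
adjacent-layer transitions in which a cell changes module; it is computed
for many {gamma, omega} samples drawn from the bounded parameter region
where community structure is non-trivial, and node ranks are averaged over
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._louvain import maximize_quality, partition_quality
from .reconstruction import CorrelationNetwork

logger = logging.getLogger("spontnet")

__all__ = [
    "MultilayerNetwork",
    "MultilayerPartition",
    "FlexibilityProfile",
    "build_multilayer",
    "multilayer_modularity",
    "maximize_multilayer",
    "flexibility",
    "estimate_parameter_bounds",
    "sample_flexibility",
]


@dataclass
class MultilayerNetwork:
    """Binary adjacencies of T >= 2 sessions over a fixed, ordered cell set."""

    node_ids: np.ndarray
    layers: list[np.ndarray]
    day_offsets: list[int]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("need at least 2 layers")
        n = len(self.node_ids)
        if any(L.shape != (n, n) for L in self.layers):
            raise ValueError("layer shapes must match the node set")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class MultilayerPartition:
    """Node x layer labels from one (gamma, omega) maximization."""

    labels: np.ndarray  # (N, T), shared label namespace
    gamma: float
    omega: float
    Q_value: float

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class FlexibilityProfile:
    """Per-node flexibility summaries over {gamma, omega} samples.

    ``mean_flexibility`` averages the raw per-sample flexibility f_i in
    [0, 1]; ``rank_mean`` averages the within-sample ranks of f_i (the
    profile used to compare nodes, robust to per-sample scale).
    """

    node_ids: np.ndarray
    mean_flexibility: np.ndarray
    rank_mean: np.ndarray
    n_samples: int
    gamma_range: tuple[float, float]
    omega_range: tuple[float, float]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_multilayer(
    networks: list[CorrelationNetwork],
    max_layers: int = 5,
) -> MultilayerNetwork:
    """Stack binary adjacencies over the intersection of all sessions' cells.

    By default the first five sessions are used (the longest run available
    in every animal of the emulated study).  Degenerate (flagged) cells are
    excluded before intersecting.
    """
    nets = networks[:max_layers]
    if len(nets) < 2:
        raise ValueError("need at least 2 sessions")
    shared = nets[0].valid_cell_ids()
    for net in nets[1:]:
        shared = np.intersect1d(shared, net.valid_cell_ids())
    if shared.size == 0:
        raise ValueError("no cells shared by all sessions")
    layers = []
    for net in nets:
        pos = {c: i for i, c in enumerate(np.asarray(net.cell_ids))}
        idx = np.array([pos[c] for c in shared])
        layers.append(net.A[np.ix_(idx, idx)].astype(float))
    return MultilayerNetwork(
        node_ids=shared,
        layers=layers,
        day_offsets=[int(net.day_offset or 0) for net in nets],
    )


# ---------------------------------------------------------------------------
# multilayer modularity
# ---------------------------------------------------------------------------

def supra_modularity_matrix(
    ml: MultilayerNetwork,
    gamma: float,
    omega: float,
    coupling: str = "ordinal",
) -> np.ndarray:
    """Supra-modularity matrix over (layer, cell) supra-nodes.

    Intra-layer blocks carry the per-layer degree null A_u - gamma k k'/2m_u
    (diagonal included, A_ii = 0); inter-layer blocks couple each cell to
    itself with weight omega in adjacent layers ("ordinal") or in all layer
    pairs ("all").
    """
    N, T = ml.n_nodes, ml.n_layers
    B = np.zeros((N * T, N * T))
    eye = np.eye(N)
    for u, A in enumerate(ml.layers):
        k = A.sum(axis=1)
        twom = k.sum()
        null = np.outer(k, k) / twom if twom > 0 else 0.0
        sl = slice(u * N, (u + 1) * N)
        B[sl, sl] = A - gamma * null
    for u in range(T):
        for v in range(T):
            if u == v:
                continue
            if coupling == "ordinal" and abs(u - v) != 1:
                continue
            B[u * N : (u + 1) * N, v * N : (v + 1) * N] += omega * eye
    return B


def _flatten(labels: np.ndarray) -> np.ndarray:
    """(N, T) labels -> supra vector indexed layer-major (u*N + i)."""
    return np.asarray(labels).T.reshape(-1)


def multilayer_modularity(
    ml: MultilayerNetwork,
    labels: np.ndarray,
    gamma: float,
    omega: float,
    coupling: str = "ordinal",
) -> float:
    """Exact multilayer modularity of a (N, T) labeling."""
    labels = np.asarray(labels)
    if labels.shape != (ml.n_nodes, ml.n_layers):
        raise ValueError("labels must be (n_nodes, n_layers)")
    B = supra_modularity_matrix(ml, gamma, omega, coupling)
    return partition_quality(B, _flatten(labels))


def maximize_multilayer(
    ml: MultilayerNetwork,
    gamma: float,
    omega: float,
    rng: np.random.Generator | int | None = None,
    n_runs: int = 10,
    coupling: str = "ordinal",
) -> MultilayerPartition:
    """Louvain-style maximization on the supra-graph of (cell, layer) nodes."""
    rng = np.random.default_rng(rng)
    B = supra_modularity_matrix(ml, gamma, omega, coupling)
    flat, q = maximize_quality(B, rng, n_runs=n_runs)
    labels = flat.reshape(ml.n_layers, ml.n_nodes).T
    return MultilayerPartition(labels=labels, gamma=gamma, omega=omega, Q_value=q)


def flexibility(labels: np.ndarray) -> np.ndarray:
    """f_i = fraction of adjacent-layer transitions where the label changes."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("labels must be (n_nodes, n_layers) with T >= 2")
    same = labels[:, 1:] == labels[:, :-1]
    return 1.0 - same.mean(axis=1)


# ---------------------------------------------------------------------------
# parameter-space bounding and sampling
# ---------------------------------------------------------------------------

def _feasible(
    ml: MultilayerNetwork,
    gamma: float,
    omega: float,
    rng: np.random.Generator,
    n_runs: int,
) -> bool:
    """Non-trivial structure: 1 < #communities < N*T and flexibility
    strictly between the all-static (0) and all-switching (1) extremes."""
    part = maximize_multilayer(ml, gamma, omega, rng=rng, n_runs=n_runs)
    nc = part.n_communities
    if not 1 < nc < ml.n_nodes * ml.n_layers:
        return False
    f = flexibility(part.labels)
    if np.all(f == 0.0) or np.all(f == 1.0):
        return False
    return True


def _bisect_edge(feas, good: float, bad: float, n_iter: int = 7) -> float:
    """Feasibility boundary between a feasible point and an infeasible one.

    Returns the last point found feasible; ``good``/``bad`` may lie on
    either side of each other.
    """
    for _ in range(n_iter):
        mid = 0.5 * (good + bad)
        if feas(mid):
            good = mid
        else:
            bad = mid
    return good


def estimate_parameter_bounds(
    ml: MultilayerNetwork,
    rng: np.random.Generator | int | None = None,
    gamma_limits: tuple[float, float] = (0.05, 5.0),
    omega_limits: tuple[float, float] = (0.0, 3.0),
    n_runs: int = 3,
    grid_points: int = 6,
    shrink: float = 0.9,
    max_shrink: int = 12,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Largest axis-aligned {gamma, omega} box with non-trivial structure.

    Feasibility (the four conditions of ``_feasible``) is probed on a coarse
    grid; the largest axis-aligned rectangle of feasible grid points is
    taken, its edges are refined by bisection toward the neighboring
    infeasible grid lines, and the box is finally shrunk toward its center
    until all four corners re-verify as feasible.  Raises with diagnostics
    if no grid point is feasible.
    """
    rng = np.random.default_rng(rng)

    def feas(g, w):
        return _feasible(ml, g, w, rng, n_runs)

    gammas = np.linspace(*gamma_limits, grid_points)
    omegas = np.linspace(*omega_limits, grid_points)
    ok = np.zeros((grid_points, grid_points), dtype=bool)
    for i, g in enumerate(gammas):
        for j, w in enumerate(omegas):
            ok[i, j] = feas(g, w)
    if not ok.any():
        raise RuntimeError(
            "no feasible (gamma, omega) found on the "
            f"{grid_points}x{grid_points} grid over gamma={gamma_limits}, "
            f"omega={omega_limits}"
        )

    # largest all-feasible rectangle of grid cells (grid is small: scan all)
    best = None
    best_area = -1.0
    for i0 in range(grid_points):
        for i1 in range(i0, grid_points):
            for j0 in range(grid_points):
                for j1 in range(j0, grid_points):
                    if ok[i0 : i1 + 1, j0 : j1 + 1].all():
                        area = (gammas[i1] - gammas[i0] + 1e-9) * (
                            omegas[j1] - omegas[j0] + 1e-9
                        )
                        if area > best_area:
                            best_area = area
                            best = (i0, i1, j0, j1)
    i0, i1, j0, j1 = best
    g_lo, g_hi = gammas[i0], gammas[i1]
    w_lo, w_hi = omegas[j0], omegas[j1]

    # refine each edge toward the adjacent infeasible grid line
    w_mid = 0.5 * (w_lo + w_hi)
    g_mid = 0.5 * (g_lo + g_hi)
    if i0 > 0:
        g_lo = _bisect_edge(lambda g: feas(g, w_mid), g_lo, gammas[i0 - 1], 4)
    if i1 < grid_points - 1:
        g_hi = _bisect_edge(lambda g: feas(g, w_mid), g_hi, gammas[i1 + 1], 4)
    if j0 > 0:
        w_lo = _bisect_edge(lambda w: feas(g_mid, w), w_lo, omegas[j0 - 1], 4)
    if j1 < grid_points - 1:
        w_hi = _bisect_edge(lambda w: feas(g_mid, w), w_hi, omegas[j1 + 1], 4)

    for _ in range(max_shrink):
        corners = [(g_lo, w_lo), (g_lo, w_hi), (g_hi, w_lo), (g_hi, w_hi)]
        if all(feas(g, w) for g, w in corners):
            return (float(g_lo), float(g_hi)), (float(w_lo), float(w_hi))
        gc, wc = 0.5 * (g_lo + g_hi), 0.5 * (w_lo + w_hi)
        g_lo = gc + shrink * (g_lo - gc)
        g_hi = gc + shrink * (g_hi - gc)
        w_lo = wc + shrink * (w_lo - wc)
        w_hi = wc + shrink * (w_hi - wc)
    logger.warning(
        "estimate_parameter_bounds: corners never all re-verified; "
        "returning shrunken box around (%.3f, %.3f)",
        0.5 * (g_lo + g_hi),
        0.5 * (w_lo + w_hi),
    )
    return (float(g_lo), float(g_hi)), (float(w_lo), float(w_hi))


def sample_flexibility(
    ml: MultilayerNetwork,
    n_samples: int = 10000,
    rng: np.random.Generator | int | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    n_runs: int = 1,
) -> FlexibilityProfile:
    """Rank-averaged node flexibility over uniform {gamma, omega} samples.

    For each sample drawn uniformly from the feasible box, multilayer
    modularity is maximized, per-node flexibility computed, nodes ranked
    within the sample, and ranks averaged across samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng)
    if bounds is None:
        bounds = estimate_parameter_bounds(ml, rng=rng)
    (g_lo, g_hi), (w_lo, w_hi) = bounds
    N = ml.n_nodes
    f_sum = np.zeros(N)
    rank_sum = np.zeros(N)
    for _ in range(n_samples):
        g = rng.uniform(g_lo, g_hi)
        w = rng.uniform(w_lo, w_hi)
        part = maximize_multilayer(ml, g, w, rng=rng, n_runs=n_runs)
        f = flexibility(part.labels)
        f_sum += f
        rank_sum += rankdata(f)
    return FlexibilityProfile(
        node_ids=ml.node_ids,
        mean_flexibility=f_sum / n_samples,
        rank_mean=rank_sum / n_samples,
        n_samples=n_samples,
        gamma_range=(float(g_lo), float(g_hi)),
        omega_range=(float(w_lo), float(w_hi)),
    )
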