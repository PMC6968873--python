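"""Day-to-day similarity of correlation and modular structure.

For each pair of sessions (u, v) the cells recorded in both are identified,
the two matrices (signed jitter-z correlation matrices W, or module
co-assignment matrices C) are restricted to those shared cells, their
strictly-upper-triangle entries are vectorized and correlated (Pearson
r_uv), and r_uv is standardized against a Mantel-style null in which the
rows and columns of one matrix are permuted by the same random node
permutation.  Aggregating z-scores over pairs and correlating them with the
day distance d_uv quantifies how quickly network structure decays in time.

The Mantel z is not symmetric in its arguments (the null permutes the first
matrix), so both orderings are computed; the pair record carries both and
their mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .modules import HierarchicalPartition, coassignment
from .reconstruction import CorrelationNetwork

logger = logging.getLogger("spontnet")

__all__ = [
    "SessionMatrix",
    "SessionPairSimilarity",
    "shared_submatrices",
    "align_matrices",
    "matrix_similarity",
    "mantel_z",
    "pairwise_similarity",
    "session_matrices_from_networks",
    "session_matrices_from_hierarchies",
    "pairs_table",
    "decay_analysis",
    "tercile_similarity",
]


@dataclass
class SessionMatrix:
    """A per-session square matrix (correlation or co-assignment) with ids."""

    session_id: str
    day_offset: int
    cell_ids: np.ndarray
    M: np.ndarray
    kind: str = "correlation"


@dataclass
class SessionPairSimilarity:
    """Similarity of one session pair's matrices over their shared cells."""

    u: str
    v: str
    n_shared_cells: int
    r_uv: float
    z_uv: float            # null permutes the u-matrix
    z_vu: float            # null permutes the v-matrix
    d_uv: int
    matrix_kind: str

    @property
    def z_mean(self) -> float:
        return 0.5 * (self.z_uv + self.z_vu)


# ---------------------------------------------------------------------------
# alignment and similarity primitives
# ---------------------------------------------------------------------------

def align_matrices(
    ids_u: np.ndarray,
    M_u: np.ndarray,
    ids_v: np.ndarray,
    M_v: np.ndarray,
    min_shared: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Restrict two matrices to their shared cells, identically ordered.

    Returns (M_u', M_v', shared_ids) or None (with a warning) when fewer
    than ``min_shared`` cells are shared.
    """
    ids_u = np.asarray(ids_u)
    ids_v = np.asarray(ids_v)
    shared = np.intersect1d(ids_u, ids_v)
    if shared.size < min_shared:
        warnings.warn(
            f"session pair skipped: only {shared.size} shared cells "
            f"(< {min_shared})",
            stacklevel=2,
        )
        return None
    # robust index lookup (ids need not be sorted)
    pos_u = {c: i for i, c in enumerate(ids_u)}
    pos_v = {c: i for i, c in enumerate(ids_v)}
    iu = np.array([pos_u[c] for c in shared])
    iv = np.array([pos_v[c] for c in shared])
    return M_u[np.ix_(iu, iu)], M_v[np.ix_(iv, iv)], shared


def shared_submatrices(
    net_u: CorrelationNetwork,
    net_v: CorrelationNetwork,
    min_shared: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Shared-cell weighted submatrices of two correlation networks.

    Cells flagged as degenerate in either network are excluded before the
    intersection.
    """
    return align_matrices(
        net_u.valid_cell_ids(),
        net_u.W[np.ix_(*2 * [_valid_idx(net_u)])],
        net_v.valid_cell_ids(),
        net_v.W[np.ix_(*2 * [_valid_idx(net_v)])],
        min_shared=min_shared,
    )


def _valid_idx(net: CorrelationNetwork) -> np.ndarray:
    mask = np.ones(net.n_cells, dtype=bool)
    mask[net.flagged_cells] = False
    return np.flatnonzero(mask)


def matrix_similarity(M_u: np.ndarray, M_v: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangle vectors."""
    M_u = np.asarray(M_u, dtype=float)
    M_v = np.asarray(M_v, dtype=float)
    if M_u.shape != M_v.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(M_u.shape[0], k=1)
    x, y = M_u[iu], M_v[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite off-diagonal pairs")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("matrix_similarity undefined: zero variance", stacklevel=2)
        return float("nan")
    return float(pearsonr(x, y)[0])


def mantel_z(
    M_u: np.ndarray,
    M_v: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation z-score of matrix similarity (Mantel-style).

    The same random node permutation is applied to rows and columns of
    ``M_u``; the null similarity is recomputed against ``M_v``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    M_u = np.asarray(M_u, dtype=float).copy()
    M_v = np.asarray(M_v, dtype=float).copy()
    n = M_u.shape[0]
    r_obs = matrix_similarity(M_u, M_v)
    # rare non-finite off-diagonal entries (degenerate edges) would wander
    # under permutation; impute them with the matrix's finite mean
    for M in (M_u, M_v):
        np.fill_diagonal(M, 0.0)
        bad = ~np.isfinite(M)
        if bad.any():
            warnings.warn(
                "mantel_z: imputing non-finite matrix entries with the mean",
                stacklevel=2,
            )
            M[bad] = M[np.isfinite(M)].mean()
    null = np.empty(n_perm)
    iu = np.triu_indices(n, k=1)
    y = M_v[iu]
    ybar = y - y.mean()
    ynorm = np.sqrt((ybar**2).sum())
    for t in range(n_perm):
        perm = rng.permutation(n)
        x = M_u[np.ix_(perm, perm)][iu]
        xbar = x - x.mean()
        null[t] = float(xbar @ ybar) / (np.sqrt((xbar**2).sum()) * ynorm)
    sd = null.std()
    if sd == 0:
        warnings.warn("mantel_z: degenerate null (zero sd)", stacklevel=2)
        return float("nan")
    return float((r_obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# pairwise drivers
# ---------------------------------------------------------------------------

def session_matrices_from_networks(
    networks: list[CorrelationNetwork],
) -> list[SessionMatrix]:
    """Signed weighted matrices W per session (flagged cells removed)."""
    out = []
    for net in networks:
        idx = _valid_idx(net)
        out.append(
            SessionMatrix(
                session_id=net.session_id or "",
                day_offset=int(net.day_offset or 0),
                cell_ids=np.asarray(net.cell_ids)[idx],
                M=net.W[np.ix_(idx, idx)],
                kind="correlation",
            )
        )
    return out


def session_matrices_from_hierarchies(
    hierarchies: list[HierarchicalPartition],
    networks: list[CorrelationNetwork],
    levels: list[list[int]] | None = None,
) -> list[SessionMatrix]:
    """Co-assignment matrices built from each session's hierarchy levels.

    ``levels[s]`` optionally restricts which (1-based) levels of session
    ``s`` enter the consensus; by default all retained levels are used.
    Sessions whose hierarchy has no significant level fall back to the
    trivial one-module partition (C = all ones) with a warning.
    """
    out = []
    for s, (hp, net) in enumerate(zip(hierarchies, networks)):
        n = hp.labels.shape[1] if hp.n_levels else net.n_cells
        use = levels[s] if levels is not None else hp.levels
        use = [l for l in use if 1 <= l <= hp.n_levels]
        if not use:
            warnings.warn(
                f"session {net.session_id}: no hierarchy level available; "
                "co-assignment matrix is trivial",
                stacklevel=2,
            )
            C = np.ones((n, n))
        else:
            C = coassignment([hp.level_labels(l) for l in use]).C
        out.append(
            SessionMatrix(
                session_id=net.session_id or "",
                day_offset=int(net.day_offset or 0),
                cell_ids=np.asarray(net.cell_ids),
                M=C,
                kind="coassignment",
            )
        )
    return out


def pairwise_similarity(
    mats: list[SessionMatrix],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_shared: int = 10,
) -> list[SessionPairSimilarity]:
    """All session-pair similarities (both Mantel orderings per pair)."""
    rng = np.random.default_rng(rng)
    pairs: list[SessionPairSimilarity] = []
    for a in range(len(mats)):
        for b in range(a + 1, len(mats)):
            u, v = mats[a], mats[b]
            aligned = align_matrices(
                u.cell_ids, u.M, v.cell_ids, v.M, min_shared=min_shared
            )
            if aligned is None:
                continue
            Mu, Mv, shared = aligned
            r = matrix_similarity(Mu, Mv)
            z_uv = mantel_z(Mu, Mv, n_perm=n_perm, rng=rng)
            z_vu = mantel_z(Mv, Mu, n_perm=n_perm, rng=rng)
            pairs.append(
                SessionPairSimilarity(
                    u=u.session_id,
                    v=v.session_id,
                    n_shared_cells=int(shared.size),
                    r_uv=r,
                    z_uv=z_uv,
                    z_vu=z_vu,
                    d_uv=abs(v.day_offset - u.day_offset),
                    matrix_kind=u.kind,
                )
            )
    return pairs


def pairs_table(pairs: list[SessionPairSimilarity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "u": [p.u for p in pairs],
            "v": [p.v for p in pairs],
            "kind": [p.matrix_kind for p in pairs],
            "n_shared": [p.n_shared_cells for p in pairs],
            "r": [p.r_uv for p in pairs],
            "z_uv": [p.z_uv for p in pairs],
            "z_vu": [p.z_vu for p in pairs],
            "z": [p.z_mean for p in pairs],
            "d": [p.d_uv for p in pairs],
        }
    )


def decay_analysis(
    pairs: list[SessionPairSimilarity],
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of pair z-scores with day distance.

    Negative values reproduce the signature of gradually reorganizing
    networks: sessions further apart in time are less similar.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 session pairs for a decay estimate")
    table = pairs_table(pairs)
    table = table[np.isfinite(table["z"]) & np.isfinite(table["d"])]
    if len(table) < 3:
        raise ValueError("fewer than 3 finite pairs")
    if table["z"].std() == 0 or table["d"].std() == 0:
        warnings.warn("decay_analysis undefined: constant z or d", stacklevel=2)
        return float("nan"), table
    r = float(pearsonr(table["z"], table["d"])[0])
    return r, table


def level_terciles(n_levels: int) -> list[list[int]]:
    """Split levels 1..L into up to three contiguous groups, coarse to fine.

    With fewer than 3 levels the terciles collapse to fewer groups (with a
    warning); e.g. 9 levels -> [1-3], [4-6], [7-9].
    """
    if n_levels < 3:
        warnings.warn(
            f"hierarchy with {n_levels} level(s): terciles collapse",
            stacklevel=2,
        )
    return [
        [int(l) for l in g]
        for g in np.array_split(np.arange(1, n_levels + 1), 3)
        if len(g)
    ]


def tercile_similarity(
    hierarchies: list[HierarchicalPartition],
    networks: list[CorrelationNetwork],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_shared: int = 10,
) -> dict[int, tuple[float, pd.DataFrame]]:
    """Decay analysis per hierarchy tercile.

    Each session's retained levels are split into up to three contiguous
    groups (coarse, middle, fine); within each tercile the co-assignment
    consensus is recomputed from just those levels and the decay analysis is
    repeated.  Sessions with fewer than 3 levels collapse to fewer groups
    (with a warning); a tercile is analyzed only across sessions that have
    it.
    """
    rng = np.random.default_rng(rng)
    per_session_groups = [level_terciles(hp.n_levels) for hp in hierarchies]

    out: dict[int, tuple[float, pd.DataFrame]] = {}
    for t in range(3):
        keep = [s for s, g in enumerate(per_session_groups) if t < len(g)]
        if len(keep) < 3:
            continue
        mats = session_matrices_from_hierarchies(
            [hierarchies[s] for s in keep],
            [networks[s] for s in keep],
            levels=[per_session_groups[s][t] for s in keep],
        )
        pairs = pairwise_similarity(
            mats, n_perm=n_perm, rng=rng, min_shared=min_shared
        )
        if len(pairs) >= 3:
            out[t + 1] = decay_analysis(pairs)
    return out
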