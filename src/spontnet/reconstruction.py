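"""Functional-network reconstruction from fluorescence traces.

Edges are Pearson correlations of *differenced* traces (differencing reduces
serial autocorrelation and makes the series approximately stationary before
correlating).  Edge significance is assessed against a jitter null: each
cell's series is independently offset by a random start index p (within the
first two seconds of recording) and truncated to length T - 2p, destroying
fine temporal alignment while preserving marginal statistics.  Correlations
that the jitter null reproduces are considered chance; the rest form a
sparse binary adjacency A (p < alpha), while the full jitter-z-scored signed
matrix W is retained for similarity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import FluorescenceSession

logger = logging.getLogger("spontnet")

__all__ = [
    "CorrelationNetwork",
    "difference_series",
    "correlation_matrix",
    "jitter_surrogate",
    "edge_significance",
    "build_network",
]


@dataclass
class CorrelationNetwork:
    """Per-session weighted and binary functional networks.

    W      jitter-z-scored signed correlations (similarity analyses)
    R_raw  Pearson correlations of differenced traces (before z-scoring)
    P      empirical two-sided p-values from the jitter null
    A      binary adjacency, A_ij = 1 iff P_ij < alpha (module/core analyses)
    """

    cell_ids: np.ndarray
    W: np.ndarray
    R_raw: np.ndarray
    P: np.ndarray
    A: np.ndarray
    n_jitter: int
    alpha: float = 0.05
    session_id: str | None = None
    day_offset: int | None = None
    flagged_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def valid_cell_ids(self) -> np.ndarray:
        """Cell ids excluding cells flagged for degenerate (zero-variance) traces."""
        mask = np.ones(self.n_cells, dtype=bool)
        mask[self.flagged_cells] = False
        return np.asarray(self.cell_ids)[mask]


def difference_series(x: np.ndarray) -> np.ndarray:
    """First differences: [x_2 - x_1, ..., x_T - x_{T-1}], length T - 1."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("series must have length >= 2 to difference")
    return np.diff(x, axis=-1)


def correlation_matrix(traces: np.ndarray) -> np.ndarray:
    """Pearson correlation of differenced traces (cells x frames).

    Rows whose differenced series has zero variance are flagged: their
    off-diagonal entries are NaN (excluded downstream) and a warning is
    logged.  Diagonal is exactly 1 for valid rows.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be a 2-D cells x frames array")
    if traces.shape[1] < 3:
        raise ValueError("need at least 3 frames")
    d = difference_series(traces)
    sd = d.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.warning(
            "correlation_matrix: %d cell(s) with zero-variance differenced "
            "traces flagged (indices %s)",
            degenerate.size,
            degenerate.tolist(),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(d)
    r = np.atleast_2d(r)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def jitter_surrogate(
    x: np.ndarray,
    rng: np.random.Generator,
    max_offset: int = 60,
) -> np.ndarray:
    """Jittered surrogate: drop a random prefix of p samples (p uniform on
    {0, ..., max_offset}) and keep the next T - 2p samples.

    ``max_offset`` defaults to 60 samples, i.e. a two-second window at the
    30 Hz frame rate.  The surrogate is returned *undifferenced*; callers
    apply the same differencing as for the originals.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if T <= 2 * max_offset:
        raise ValueError(
            f"series too short for jittering: T={T} <= 2*max_offset={2 * max_offset}"
        )
    p = int(rng.integers(0, max_offset + 1))
    return x[p : T - p]


def edge_significance(
    traces: np.ndarray,
    n_jitter: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    max_offset: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jitter-null edge test for all cell pairs.

    Each repetition independently jitters every cell's series, re-differences,
    and recomputes the full correlation matrix on the common truncated length.
    Returns (W, P, A) where

        P_ij = (1 + #{|r_jitter| >= |r_obs|}) / (1 + n_jitter)   (two-sided)
        W_ij = (r_obs - mean(r_jitter)) / sd(r_jitter)
        A_ij = 1[P_ij < alpha], zero diagonal.

    The test is two-sided on |r| so that anticorrelations can also be
    significant; the +1 pseudocount keeps p-values strictly positive.
    """
    if n_jitter < 100:
        raise ValueError("n_jitter must be >= 100")
    rng = np.random.default_rng(rng)
    traces = np.asarray(traces, dtype=float)
    N, T = traces.shape
    if T <= 2 * max_offset:
        raise ValueError(
            f"traces too short for jittering: T={T} <= 2*max_offset={2 * max_offset}"
        )

    r_obs = correlation_matrix(traces)
    sd_diff = np.diff(traces, axis=1).std(axis=1)
    flagged = np.flatnonzero(sd_diff == 0)

    abs_obs = np.abs(r_obs)
    count_ge = np.zeros((N, N))
    acc_sum = np.zeros((N, N))
    acc_sq = np.zeros((N, N))
    cols = np.arange(N)[:, None]
    for _ in range(n_jitter):
        p = rng.integers(0, max_offset + 1, size=N)
        L = T - 2 * int(p.max())  # common truncated length
        idx = p[:, None] + np.arange(L)[None, :]
        seg = traces[cols, idx]
        d = np.diff(seg, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(d)
        r = np.atleast_2d(r)
        with np.errstate(invalid="ignore"):
            count_ge += np.abs(r) >= abs_obs
        acc_sum += np.nan_to_num(r)
        acc_sq += np.nan_to_num(r) ** 2

    P = (1.0 + count_ge) / (1.0 + n_jitter)
    mean_j = acc_sum / n_jitter
    var_j = np.maximum(acc_sq / n_jitter - mean_j**2, 0.0)
    sd_j = np.sqrt(var_j)
    zero_sd = (sd_j == 0) & ~np.eye(N, dtype=bool)
    if np.any(zero_sd[np.triu_indices(N, 1)]):
        logger.warning(
            "edge_significance: %d pair(s) with zero jitter sd; W undefined",
            int(zero_sd[np.triu_indices(N, 1)].sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        W = (r_obs - mean_j) / sd_j
    W[zero_sd] = np.nan

    A = (P < alpha).astype(int)
    np.fill_diagonal(A, 0)
    np.fill_diagonal(P, np.nan)
    np.fill_diagonal(W, np.nan)
    if flagged.size:
        for M in (P, W):
            M[flagged, :] = np.nan
            M[:, flagged] = np.nan
        A[flagged, :] = 0
        A[:, flagged] = 0
    return W, P, A


def build_network(
    session: FluorescenceSession,
    n_jitter: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    max_offset: int | None = None,
) -> CorrelationNetwork:
    """Full per-session reconstruction: R_raw, jitter-z W, p-values, binary A."""
    if max_offset is None:
        max_offset = int(round(2.0 * session.sampling_rate_hz))
    R_raw = correlation_matrix(session.traces)
    W, P, A = edge_significance(
        session.traces,
        n_jitter=n_jitter,
        alpha=alpha,
        rng=rng,
        max_offset=max_offset,
    )
    sd_diff = np.diff(session.traces, axis=1).std(axis=1)
    flagged = np.flatnonzero(sd_diff == 0)
    return CorrelationNetwork(
        cell_ids=np.asarray(session.cell_ids),
        W=W,
        R_raw=R_raw,
        P=P,
        A=A,
        n_jitter=n_jitter,
        alpha=alpha,
        session_id=session.session_id,
        day_offset=session.day_offset,
        flagged_cells=flagged,
    )
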