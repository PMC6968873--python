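"""Generalized Louvain engine.

Maximizes partition quality of the form

    Q = sum_ij B_ij * delta(g_i, g_j)

over all ordered pairs (i, j), *including* i == j, for an arbitrary dense
symmetric modularity matrix ``B``.  Diagonal entries therefore contribute a
partition-independent constant (every node always shares a module with
itself), so they never change the argmax but are kept in the reported value
so that algebraic identities (e.g. the one-module partition scoring exactly
zero at resolution 1) hold exactly.

The same engine serves single-layer modularity (B = A - gamma*k k'/2m) and
multilayer supra-modularity (block-diagonal per-layer nulls plus inter-layer
coupling), which is why it lives outside the public modules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["partition_quality", "maximize_quality"]

_TOL = 1e-12


def partition_quality(B: np.ndarray, labels: np.ndarray) -> float:
    """Evaluate Q = sum_ij B_ij delta(g_i, g_j) (ordered pairs, i == j included)."""
    labels = np.asarray(labels)
    if labels.shape[0] != B.shape[0]:
        raise ValueError("labels length does not match matrix size")
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        q += B[np.ix_(idx, idx)].sum()
    return float(q)


def _compact(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as consecutive integers, ordered by first occurrence."""
    _, inv = np.unique(labels, return_inverse=True)
    # np.unique sorts by value; re-order by first appearance for determinism
    order = {}
    out = np.empty_like(inv)
    nxt = 0
    for i, c in enumerate(inv):
        if c not in order:
            order[c] = nxt
            nxt += 1
        out[i] = order[c]
    return out


def _move_phase(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy local moving from all-singletons; ties broken toward the
    lowest community index (argmax returns the first maximum)."""
    n = B.shape[0]
    labels = np.arange(n)
    counts = np.ones(n, dtype=int)
    diag = np.diag(B).copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            cur = labels[i]
            row = B[i]
            # s[c] = sum of B_ij over j != i currently in community c
            s = np.bincount(labels, weights=row, minlength=n)
            s[cur] -= diag[i]
            best = int(np.argmax(s))
            stay = s[cur]
            # a fresh singleton community scores 0 (only a real option when
            # the node currently has company)
            if s[best] > stay + _TOL and best != cur:
                counts[cur] -= 1
                counts[best] += 1
                labels[i] = best
                improved = True
            elif s[best] <= _TOL and stay < -_TOL and counts[cur] > 1:
                empty = int(np.flatnonzero(counts == 0)[0])
                counts[cur] -= 1
                counts[empty] += 1
                labels[i] = empty
                improved = True
    return _compact(labels)


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = int(labels.max()) + 1
    C = np.zeros((B.shape[0], k))
    C[np.arange(B.shape[0]), labels] = 1.0
    return C.T @ B @ C


def _one_run(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = B.shape[0]
    node_to_comm = np.arange(n)
    M = B
    while True:
        local = _move_phase(M, rng)
        n_comm = int(local.max()) + 1
        if n_comm == M.shape[0]:  # no merges: converged
            break
        node_to_comm = local[node_to_comm]
        M = _aggregate(M, local)
        if n_comm == 1:
            break
    return _compact(node_to_comm)


def maximize_quality(
    B: np.ndarray,
    rng: np.random.Generator,
    n_runs: int = 10,
) -> tuple[np.ndarray, float]:
    """Best-of-``n_runs`` generalized Louvain.

    Returns ``(labels, Q)``.  The returned Q is guaranteed to be at least
    that of the all-singletons and the one-module partitions (both are
    checked explicitly and substituted if the search did worse).
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be a square matrix")
    n = B.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    best_labels = np.zeros(n, dtype=int)
    best_q = partition_quality(B, best_labels)  # one module
    singles = np.arange(n)
    q_singles = partition_quality(B, singles)
    if q_singles > best_q:
        best_labels, best_q = singles, q_singles
    for _ in range(max(1, n_runs)):
        labels = _one_run(B, rng)
        q = partition_quality(B, labels)
        if q > best_q + _TOL:
            best_labels, best_q = labels, q
    return best_labels, best_q
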