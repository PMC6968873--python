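"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, full enumeration) and
shares no code with the package's optimized implementations.
"""

import itertools

import numpy as np


def set_partitions(n):
    """All partitions of {0..n-1} in restricted-growth-string form."""
    if n == 0:
        return
    if n == 1:
        yield [0]
        return
    for p in set_partitions(n - 1):
        m = max(p)
        for c in range(m + 2):
            yield p + [c]


def all_partitions_array(n):
    return np.array(list(set_partitions(n)), dtype=int)


def brute_modularity(A, labels, gamma):
    """Double loop over all ordered pairs, i == j included (A_ii = 0)."""
    n = A.shape[0]
    k = [sum(A[i][j] for j in range(n)) for i in range(n)]
    twom = sum(k)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i][j] - gamma * k[i] * k[j] / twom
    return q


def brute_multilayer_modularity(layers, labels, gamma, omega):
    """Quadruple loop: per-layer degree null plus ordinal coupling.

    ``labels`` is (n_nodes, n_layers); ordered adjacent layer pairs (u, u+1)
    and (u+1, u) each contribute omega when the node keeps its label.
    """
    n, T = labels.shape
    q = 0.0
    for u, A in enumerate(layers):
        k = [sum(A[i][j] for j in range(n)) for i in range(n)]
        twom = sum(k)
        for i in range(n):
            for j in range(n):
                if labels[i, u] == labels[j, u]:
                    null = gamma * k[i] * k[j] / twom if twom > 0 else 0.0
                    q += A[i][j] - null
    for i in range(n):
        for u in range(T):
            for v in range(T):
                if abs(u - v) == 1 and labels[i, u] == labels[i, v]:
                    q += omega
    return q


def exhaustive_max_quality(B):
    """Max over every partition of Q = sum_ij B_ij delta(g_i, g_j)."""
    n = B.shape[0]
    P = all_partitions_array(n)
    q = np.zeros(len(P))
    for c in range(n):
        M = (P == c).astype(float)
        q += np.einsum("ki,ij,kj->k", M, B, M)
    return float(q.max())


def brute_core_quality(G, coreness):
    n = G.shape[0]
    r = 0.0
    for i in range(n):
        for j in range(n):
            r += G[i][j] * coreness[i] * coreness[j]
    return r


def exhaustive_max_core_quality(G, template):
    """Max of R over all N! assignments of the template to nodes."""
    n = G.shape[0]
    perms = np.array(list(itertools.permutations(range(n))))
    C = template[perms]
    R = np.einsum("ki,ij,kj->k", C, G, C)
    return float(R.max())


def pearson_by_hand(x, y):
    """Textbook Pearson formula with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def random_graph(rng, n, p):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T
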