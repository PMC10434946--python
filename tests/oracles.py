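"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with embaudit.metrics: neighbors come from
an explicit per-pair loop sorted by (distance, index), cliques from a
grow-by-higher-index enumeration of *all* cliques followed by an explicit
maximality check.
"""

import numpy as np


def brute_knn(X, k, metric="L2"):
    """k nearest neighbors by exhaustive pair enumeration."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    idx = np.empty((n, k), dtype=int)
    dists = np.empty((n, k))
    for i in range(n):
        pairs = []
        for j in range(n):
            if j == i:
                continue
            diff = X[i] - X[j]
            d = np.abs(diff).sum() if metric == "L1" else float(np.sqrt((diff ** 2).sum()))
            pairs.append((d, j))
        pairs.sort()
        dists[i] = [p[0] for p in pairs[:k]]
        idx[i] = [p[1] for p in pairs[:k]]
    return idx, dists


def brute_equidistant_groups(dists, target, epsilon, size_min=3, size_max=8):
    """Maximal band-graph cliques via exhaustive clique enumeration."""
    n = dists.shape[0]
    lo, hi = target * (1 - epsilon), target * (1 + epsilon)
    adj = (dists >= lo) & (dists <= hi)
    np.fill_diagonal(adj, False)

    cliques = []

    def grow(members):
        extendable = False
        start = members[-1] + 1
        for v in range(start, n):
            if all(adj[v, m] for m in members):
                extendable = True
                grow(members + [v])
        cliques.append(list(members))

    for v in range(n):
        grow([v])

    maximal = []
    for c in cliques:
        if len(c) < size_min:
            continue
        if any(all(adj[v, m] for m in c) for v in range(n) if v not in c):
            continue  # not maximal
        maximal.append(tuple(sorted(c))[:size_max])
    return sorted(set(maximal), key=lambda m: (len(m), m))
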