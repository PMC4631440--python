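"""Independent brute-force oracles used by the test suite.

Everything here is deliberately literal and slow: double loops over pairs,
union-find over explicit edges, breadth-first search over adjacency lists.
Nothing imports the package's fast paths, so agreement between these
functions and the library is a genuine dual-route check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def oracle_adjacency(values, zeta):
    """Literal pairwise rule: i~j iff x_i - zeta <= x_j <= x_i + zeta, i != j."""
    x = np.asarray(values, dtype=float)
    n = x.size
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and (x[i] - zeta) <= x[j] <= (x[i] + zeta):
                adj[i, j] = True
    return adj


def oracle_degrees(values, zeta):
    return oracle_adjacency(values, zeta).sum(axis=1)


def oracle_edge_count(values, zeta):
    return int(oracle_adjacency(values, zeta).sum()) // 2


def oracle_components(values, zeta):
    """Connected components as a set of frozensets of indices (via BFS)."""
    adj = oracle_adjacency(values, zeta)
    n = adj.shape[0]
    seen = [False] * n
    comps = set()
    for start in range(n):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            u = queue.popleft()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(int(v))
        comps.add(frozenset(comp))
    return comps


def components_from_labels(labels):
    """Convert a label vector into the same set-of-frozensets form."""
    groups = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    return {frozenset(g) for g in groups.values()}


def oracle_giant_size(values, zeta):
    return max(len(c) for c in oracle_components(values, zeta))


def oracle_all_pairs_hops(values, zeta):
    """All-pairs BFS hop counts; -1 for disconnected pairs."""
    adj = oracle_adjacency(values, zeta)
    n = adj.shape[0]
    neighbors = [np.nonzero(adj[i])[0] for i in range(n)]
    dist = np.full((n, n), -1, dtype=int)
    for src in range(n):
        dist[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in neighbors[u]:
                if dist[src, v] < 0:
                    dist[src, v] = dist[src, u] + 1
                    queue.append(int(v))
    return dist


def oracle_mode(values, zeta):
    """(mode value, max degree) by the tie-averaging rule on brute degrees."""
    x = np.asarray(values, dtype=float)
    deg = oracle_degrees(x, zeta)
    dmax = int(deg.max())
    tied = x[deg == dmax]
    return float(tied.mean()), dmax


def oracle_variance_two_pass(values):
    """Two-pass sample variance with denominator n - 1."""
    x = np.asarray(values, dtype=float)
    mean = sum(x) / len(x)
    return sum((v - mean) ** 2 for v in x) / (len(x) - 1)


def random_instance(seed, max_n=300):
    """A varied random test instance: (values, zeta).

    Mixes unimodal, bimodal, heavy-tailed, and duplicate-laden samples so
    cluster structure varies; zeta spans sub-gap to near-range scales.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    kind = rng.integers(0, 4)
    if kind == 0:
        values = rng.normal(100, 20, size=n)
    elif kind == 1:
        values = np.where(rng.random(n) < 0.5,
                          rng.normal(0, 1, size=n), rng.normal(10, 1, size=n))
    elif kind == 2:
        values = rng.lognormal(1, 0.8, size=n)
    else:
        values = np.round(rng.normal(50, 5, size=n))  # many exact duplicates
    spread = values.max() - values.min()
    zeta = float(rng.uniform(0, 1.2) * (spread if spread > 0 else 1.0) * rng.choice([0.01, 0.05, 0.3, 1.0]))
    return values, zeta
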