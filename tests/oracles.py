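"""Independent oracles used across the test suite.

Each oracle deliberately avoids the code path it checks: the
hypergeometric oracles count subsets directly (or sum exact binomial
terms with integer arithmetic), the core-decomposition oracle peels by
repeated minimum degree, and the walk oracle solves the stationary linear
system instead of iterating.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def enumerate_hypergeom_upper(M: int, K: int, N: int, x: int) -> Fraction:
    """P(X >= x) by brute-force enumeration of all C(M, N) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(M), N):
        total += 1
        if len(marked.intersection(draw)) >= x:
            hits += 1
    return Fraction(hits, total)


def exact_hypergeom_upper(M: int, K: int, N: int, x: int) -> Fraction:
    """P(X >= x) as an exact rational from the counting formula."""
    num = sum(comb(K, i) * comb(M - K, N - i) for i in range(x, min(K, N) + 1))
    return Fraction(num, comb(M, N))


def exact_hypergeom_lower(M: int, K: int, N: int, x: int) -> Fraction:
    """The cumulative sum_{i<=x} C(K,i) C(M-K,N-i) / C(M,N), exactly."""
    num = sum(comb(K, i) * comb(M - K, N - i) for i in range(0, x + 1))
    return Fraction(num, comb(M, N))


def peel_core_numbers(graph) -> dict:
    """Core numbers by repeated minimum-degree peeling (Matula–Beck)."""
    deg = {v: d for v, d in graph.degree()}
    adj = {v: set(graph.neighbors(v)) for v in graph}
    remaining = set(graph.nodes)
    core: dict = {}
    k = 0
    while remaining:
        v = min(remaining, key=lambda u: (deg[u], u))
        k = max(k, deg[v])
        core[v] = k
        remaining.remove(v)
        for u in adj[v]:
            if u in remaining:
                deg[u] -= 1
                adj[u].discard(v)
    return core


def peeling_vertex_weights(graph) -> dict:
    """MCODE vertex weights recomputed from the peeling oracle."""
    weights: dict = {}
    for v in graph:
        h = graph.subgraph(list(graph.neighbors(v)) + [v])
        core = peel_core_numbers(h)
        k_max = max(core.values())
        if k_max < 2:
            weights[v] = 0.0
            continue
        nodes = [u for u, c in core.items() if c >= k_max]
        s = h.subgraph(nodes)
        nn, ee = s.number_of_nodes(), s.number_of_edges()
        weights[v] = k_max * (2.0 * ee / (nn * (nn - 1)))
    return weights


def stationary_rwr(w: np.ndarray, p0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form stationary vector r (I - (1-r) W)^{-1} p0."""
    n = w.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * w, p0)


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
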