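"""Random walk with restart on the ceRNA network and permutation testing.

The walk iterates P(t+1) = (1 - r) W P(t) + r P0, with W the
column-normalized adjacency of the undirected tripartite graph and P0 the
(normalized) indicator of the seed genes. Statistical significance of a
lncRNA's stationary score comes from a degree-preserving permutation null:
seed sets are resampled without replacement from the gene nodes with the
same degree multiset as the real seeds, and the empirical p-value is the
fraction of permutations whose score strictly exceeds the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import LMMACNetwork
from .ppi import Module

logger = logging.getLogger("lmmacnet")


@dataclass(frozen=True)
class RWRConfig:
    r: float = 0.7          # restart probability per step
    tol: float = 1e-10      # L1 change per iteration at convergence
    max_iter: int = 1000
    normalize_seeds: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError("restart probability r must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class RWRResult:
    scores: Mapping[str, float]
    seeds: frozenset[str]
    iterations_used: int
    converged: bool
    restart: float


@dataclass(frozen=True)
class PermutationResult:
    lncrna_id: str
    observed_score: float
    m: int  # permutations scoring strictly higher than observed
    n: int  # permutations run
    p_empirical: float


@dataclass(frozen=True)
class LncrnaModuleMap:
    edges: frozenset[tuple[str, int]]  # (lncrna_id, module_rank)
    flagged: frozenset[str]


def _node_order(net: LMMACNetwork) -> list[str]:
    return sorted(net.genes) + sorted(net.mirnas) + sorted(net.lncrnas)


def column_normalized_adjacency(net: LMMACNetwork,
                                order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Column-stochastic W of the undirected tripartite graph.

    Zero-degree columns (possible only in degenerate inputs) receive a
    self-loop before normalization so W stays column-stochastic.
    """
    order = list(order) if order is not None else _node_order(net)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v in list(net.gm_edges) + list(net.ml_edges):
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    colsum = a.sum(axis=0)
    for j in np.flatnonzero(colsum == 0):
        a[j, j] = 1.0
    colsum = a.sum(axis=0)
    return a / colsum, order


def _iterate(w: np.ndarray, p0: np.ndarray, r: float, tol: float,
             max_iter: int) -> tuple[np.ndarray, int, bool]:
    """Power iteration of the restart update; ``p0`` may hold several walks
    as columns, iterated jointly until the worst column converges."""
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (w @ p) + r * p0
        delta = np.abs(p_next - p).sum(axis=0).max()
        p = p_next
        if delta < tol:
            return p, it, True
    return p, max_iter, False


def rwr(net: LMMACNetwork, seeds: set[str], cfg: RWRConfig = RWRConfig()) -> RWRResult:
    """Stationary visiting probabilities from the given seed genes.

    Seeds absent from the network are dropped with a warning; no seed in
    the network is a hard error. P0 is uniform over the retained seeds
    (mass 1/|seeds|) unless ``normalize_seeds`` is off, in which case each
    seed gets mass 1 (rankings are identical, scores scale linearly).
    """
    retained = set(seeds) & net.genes
    dropped = set(seeds) - retained
    if dropped:
        logger.warning("rwr seeds_dropped=%d (absent from network)", len(dropped))
    if not retained:
        raise ValueError("no seed gene present in the network")
    w, order = column_normalized_adjacency(net)
    idx = {n: i for i, n in enumerate(order)}
    p0 = np.zeros(len(order))
    mass = 1.0 / len(retained) if cfg.normalize_seeds else 1.0
    for s in retained:
        p0[idx[s]] = mass
    p, its, converged = _iterate(w, p0[:, None], cfg.r, cfg.tol, cfg.max_iter)
    p = p[:, 0]
    residual = np.abs((1.0 - cfg.r) * (w @ p) + cfg.r * p0 - p).sum()
    if converged and residual > cfg.tol * 10:
        raise AssertionError(f"fixed-point residual {residual} exceeds tolerance")
    return RWRResult(scores={n: float(p[idx[n]]) for n in order},
                     seeds=frozenset(retained), iterations_used=its,
                     converged=converged, restart=cfg.r)


def degree_matched_seed_sample(net: LMMACNetwork, seeds: set[str],
                               rng: np.random.Generator) -> set[str]:
    """Sample |seeds| distinct gene nodes matching the seeds' degree multiset.

    Sampling is without replacement over all gene-class nodes. When a
    degree class is too small, the shortfall is matched by nearest degree
    (ties broken at random) and the number of inexact matches is logged.
    """
    universe = sorted(net.genes)
    if len(universe) < len(seeds):
        raise ValueError("fewer gene nodes than seeds")
    g = net.to_nx()
    degree = {v: g.degree(v) for v in universe}
    by_degree: dict[int, list[str]] = {}
    for v in universe:
        by_degree.setdefault(degree[v], []).append(v)
    need: dict[int, int] = {}
    for s in sorted(seeds):
        need[degree[s]] = need.get(degree[s], 0) + 1
    chosen: set[str] = set()
    shortfall: list[int] = []
    for d in sorted(need):
        pool = [v for v in by_degree.get(d, []) if v not in chosen]
        k = min(need[d], len(pool))
        if k:
            picked = rng.choice(len(pool), size=k, replace=False)
            chosen.update(pool[i] for i in picked)
        shortfall.extend([d] * (need[d] - k))
    n_inexact = len(shortfall)
    for d in shortfall:
        pool = [v for v in universe if v not in chosen]
        dist = np.array([abs(degree[v] - d) for v in pool])
        best = np.flatnonzero(dist == dist.min())
        chosen.add(pool[best[rng.integers(len(best))]])
    if n_inexact:
        logger.warning("degree_matched_seed_sample inexact_matches=%d", n_inexact)
    return chosen


def permutation_pvalues(net: LMMACNetwork, seeds: set[str],
                        cfg: RWRConfig, n: int,
                        rng: np.random.Generator,
                        pseudocount: bool = False) -> list[PermutationResult]:
    """Empirical per-lncRNA p-values from n degree-matched seed permutations.

    For each lncRNA, m counts permutations whose score is STRICTLY greater
    than the observed score and p = m / n (ties do not count against the
    lncRNA). ``pseudocount`` switches to (m + 1) / (n + 1) for users who
    need a nonzero p floor. All permutations share one walk matrix and are
    iterated as a batch.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    retained = set(seeds) & net.genes
    if not retained:
        raise ValueError("no seed gene present in the network")
    w, order = column_normalized_adjacency(net)
    idx = {v: i for i, v in enumerate(order)}
    mass = 1.0 / len(retained) if cfg.normalize_seeds else 1.0

    p0_obs = np.zeros(len(order))
    for s in retained:
        p0_obs[idx[s]] = mass
    perm_seeds = [degree_matched_seed_sample(net, retained, rng) for _ in range(n)]
    p0 = np.zeros((len(order), n + 1))
    p0[:, 0] = p0_obs
    for j, ps in enumerate(perm_seeds, start=1):
        for s in ps:
            p0[idx[s], j] = mass
    p, _, converged = _iterate(w, p0, cfg.r, cfg.tol, cfg.max_iter)
    if not converged:
        logger.warning("permutation_pvalues walks not fully converged at max_iter")

    lnc_rows = [idx[l] for l in sorted(net.lncrnas)]
    observed = p[lnc_rows, 0]
    permuted = p[lnc_rows, 1:]
    m = (permuted > observed[:, None]).sum(axis=1)
    results = []
    for (l, obs, mm) in zip(sorted(net.lncrnas), observed, m):
        pe = (int(mm) + 1) / (n + 1) if pseudocount else int(mm) / n
        results.append(PermutationResult(lncrna_id=l, observed_score=float(obs),
                                         m=int(mm), n=n, p_empirical=float(pe)))
    results.sort(key=lambda r: (r.p_empirical, -r.observed_score, r.lncrna_id))
    return results


def lncrna_module_map(candidates: Sequence[PermutationResult],
                      net: LMMACNetwork,
                      modules: Sequence[Module],
                      perm_p_max: float = 0.05,
                      min_modules_flag: int = 3) -> LncrnaModuleMap:
    """Link each significant candidate lncRNA to the modules holding the
    genes it competes with; flag lncRNAs touching >= ``min_modules_flag``
    modules (default 3, i.e. "more than two")."""
    passing = [c for c in candidates if c.p_empirical < perm_p_max]
    if not passing:
        logger.warning("lncrna_module_map: no candidate passes perm_p_max=%g", perm_p_max)
        return LncrnaModuleMap(edges=frozenset(), flagged=frozenset())
    edges: set[tuple[str, int]] = set()
    for c in passing:
        competing = net.genes_of_lncrna(c.lncrna_id)
        for mod in modules:
            if competing & mod.members:
                edges.add((c.lncrna_id, mod.rank))
    counts: dict[str, int] = {}
    for l, _ in edges:
        counts[l] = counts.get(l, 0) + 1
    flagged = frozenset(l for l, k in counts.items() if k >= min_modules_flag)
    return LncrnaModuleMap(edges=frozenset(edges), flagged=flagged)


def write_ranking(results: Sequence[PermutationResult],
                  mapping: LncrnaModuleMap | None, path, restart: float) -> None:
    """Ranking TSV: lncrna, observed_score, m, n, p_empirical, n_modules, flagged."""
    n_mod: dict[str, int] = {}
    flagged: frozenset[str] = frozenset()
    if mapping is not None:
        for l, _ in mapping.edges:
            n_mod[l] = n_mod.get(l, 0) + 1
        flagged = mapping.flagged
    with open(path, "w") as fh:
        fh.write(f"# restart_probability={restart}\n")
        fh.write("lncrna\tobserved_score\tm\tn\tp_empirical\tn_modules\tflagged\n")
        for r in results:
            fh.write(f"{r.lncrna_id}\t{r.observed_score!r}\t{r.m}\t{r.n}\t"
                     f"{r.p_empirical!r}\t{n_mod.get(r.lncrna_id, 0)}\t"
                     f"{int(r.lncrna_id in flagged)}\n")
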