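"""PPI network construction and MCODE-style dense-module detection.

The module detector follows the Molecular Complex Detection scheme: each
vertex is weighted by the density of the highest k-core of its closed
neighborhood times that core's order, complexes are grown greedily from
high-weight seeds, and each complex is post-processed by a k-core filter.
Edge confidence scores gate network construction only; the clustering
itself is unweighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lmmacnet")


@dataclass(frozen=True)
class PPINetwork:
    """Undirected gene graph with per-edge confidence in [0, 1]."""

    graph: nx.Graph
    min_confidence: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class Module:
    """A dense connected gene subgraph with its MCODE score (density x size)."""

    members: frozenset[str]
    score: float
    rank: int
    seed: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    fdr: float


def build_ppi(edges: Iterable[tuple[str, str, float]], min_confidence: float) -> PPINetwork:
    """Build the PPI network keeping only edges with score >= ``min_confidence``.

    Self-loops are dropped; an edge listed in both directions (or repeated)
    is stored once with its maximum confidence; isolated nodes never enter.
    """
    g = nx.Graph()
    n_below = n_self = 0
    for u, v, score in edges:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"confidence score {score} outside [0, 1] for edge ({u}, {v})")
        if u == v:
            n_self += 1
            continue
        if score < min_confidence:
            n_below += 1
            continue
        if g.has_edge(u, v):
            g[u][v]["confidence"] = max(g[u][v]["confidence"], score)
        else:
            g.add_edge(u, v, confidence=score)
    if n_self:
        logger.info("build_ppi self_loops_dropped=%d", n_self)
    logger.info("build_ppi edges_below_threshold=%d edges_kept=%d",
                n_below, g.number_of_edges())
    if g.number_of_edges() == 0:
        logger.warning("build_ppi produced an empty network (all edges below threshold?)")
    return PPINetwork(graph=g, min_confidence=min_confidence)


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mcode_vertex_weights(net: PPINetwork | nx.Graph) -> dict[str, float]:
    """Weight each vertex by k_max * density of the highest k-core of its
    closed neighborhood; 0 when that neighborhood has no 2-core."""
    g = net.graph if isinstance(net, PPINetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights: dict[str, float] = {}
    for v in g.nodes:
        nbhd = list(g.neighbors(v)) + [v]
        h = g.subgraph(nbhd)
        core = nx.core_number(h)
        k_max = max(core.values())
        if k_max < 2:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core.items() if c >= k_max]
        sub = h.subgraph(core_nodes)
        weights[v] = k_max * _density(sub.number_of_nodes(), sub.number_of_edges())
    return weights


def mcode_find_modules(net: PPINetwork | nx.Graph, *,
                       degree_cutoff: int = 2,
                       node_score_cutoff: float = 0.2,
                       kcore: int = 2,
                       max_depth: int = 100,
                       fluff: bool = False,
                       fluff_density: float = 0.2,
                       haircut: bool = False,
                       min_size: int = 3) -> list[Module]:
    """Greedy complex expansion from high-weight seeds.

    Vertices with degree < ``degree_cutoff`` cannot seed. Expansion is
    breadth-first from the seed up to ``max_depth`` hops, including vertices
    whose weight >= seed weight * (1 - node_score_cutoff); each vertex joins
    at most one complex. Each complex is then reduced to its ``kcore``-core
    and discarded if fewer than ``min_size`` vertices survive. ``haircut``
    additionally removes singly-connected vertices; ``fluff`` adds unassigned
    boundary vertices whose closed-neighborhood density exceeds
    ``fluff_density`` (and can make complexes overlap, as in the original
    tool); both default off. Modules are sorted by score (density x size)
    descending, ties broken by lexicographically smallest seed id.
    """
    g = net.graph if isinstance(net, PPINetwork) else net
    if g.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    raw: list[tuple[set[str], str]] = []
    for seed in order:
        if seed in assigned or g.degree(seed) < degree_cutoff:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        complex_nodes = {seed}
        assigned.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt: list[str] = []
            for u in frontier:
                for w in sorted(g.neighbors(u)):
                    if w in assigned:
                        continue
                    if weights[w] >= threshold:
                        assigned.add(w)
                        complex_nodes.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        raw.append((complex_nodes, seed))

    modules: list[tuple[frozenset[str], float, str]] = []
    for complex_nodes, seed in raw:
        sub = nx.k_core(g.subgraph(complex_nodes), kcore)
        members = set(sub.nodes)
        if haircut and members:
            h = g.subgraph(members).copy()
            pruned = [v for v in h if h.degree(v) < 2]
            while pruned:
                h.remove_nodes_from(pruned)
                pruned = [v for v in h if h.degree(v) < 2]
            members = set(h.nodes)
        if fluff and members:
            boundary = {w for v in members for w in g.neighbors(v)} - members - assigned
            for w in sorted(boundary):
                nb = list(g.neighbors(w)) + [w]
                h = g.subgraph(nb)
                if _density(h.number_of_nodes(), h.number_of_edges()) > fluff_density:
                    members.add(w)
        if len(members) < min_size:
            continue
        sub = g.subgraph(members)
        score = _density(sub.number_of_nodes(), sub.number_of_edges()) * len(members)
        modules.append((frozenset(members), score, seed))

    modules.sort(key=lambda m: (-m[1], m[2]))
    return [Module(members=m, score=s, rank=i + 1, seed=seed)
            for i, (m, s, seed) in enumerate(modules)]


def ora_enrichment(query: set[str], gene_sets: Mapping[str, set[str]],
                   background: set[str]) -> list[EnrichmentRow]:
    """Flat over-representation test of ``query`` against each gene set.

    Each set is intersected with the background; p is the upper-tail
    hypergeometric probability of an overlap at least as large as observed,
    and FDR is Benjamini–Hochberg across all tested sets. Rows come back
    sorted by p (ties by set name).
    """
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    extra = query - background
    if extra:
        logger.warning("ora_enrichment query_ids_outside_background=%d", len(extra))
        query = query & background
        if not query:
            raise ValueError("no query genes inside the background")
    names = sorted(gene_sets)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    bg_n = len(background)
    q_n = len(query)
    for name in names:
        members = gene_sets[name] & background
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, bg_n, len(members), q_n))
        pvals.append(min(1.0, p))
        rows.append(EnrichmentRow(set_name=name, overlap=overlap,
                                  set_size=len(members), query_size=q_n,
                                  background_size=bg_n, p=min(1.0, p), fdr=1.0))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    rows = [EnrichmentRow(r.set_name, r.overlap, r.set_size, r.query_size,
                          r.background_size, r.p, float(q))
            for r, q in zip(rows, fdr)]
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def write_modules(modules: Sequence[Module], path) -> None:
    """Module TSV: rank, score, comma-joined members (sorted)."""
    with open(path, "w") as fh:
        fh.write("module_rank\tscore\tmembers\n")
        for m in modules:
            fh.write(f"{m.rank}\t{m.score:.6g}\t{','.join(sorted(m.members))}\n")


def read_modules(path) -> list[Module]:
    modules: list[Module] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            rank, score, members = line.rstrip("\n").split("\t")
            mem = frozenset(members.split(","))
            modules.append(Module(members=mem, score=float(score),
                                  rank=int(rank), seed=min(mem)))
    return modules
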