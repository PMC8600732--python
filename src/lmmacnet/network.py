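"""Tripartite ceRNA network assembly and descriptive pair counts.

The network links genes to miRNAs and miRNAs to lncRNAs; gene–lncRNA and
within-class edges never exist. Every edge derives from at least one
competing triplet (gene, miRNA, lncRNA), and triplets are materialized
explicitly because the downstream lncRNA-to-module mapping needs to know
which gene each lncRNA competes with.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .pairs import CompetingPair

logger = logging.getLogger("lmmacnet")


@dataclass(frozen=True)
class LMMACNetwork:
    genes: frozenset[str]
    mirnas: frozenset[str]
    lncrnas: frozenset[str]
    gm_edges: frozenset[tuple[str, str]]  # (gene, miRNA)
    ml_edges: frozenset[tuple[str, str]]  # (miRNA, lncRNA)
    triplets: frozenset[tuple[str, str, str]]  # (gene, miRNA, lncRNA)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.genes & self.mirnas) or (self.genes & self.lncrnas) or (self.mirnas & self.lncrnas):
            raise ValueError("node classes must be disjoint")
        gm_from_triplets = {(g, m) for g, m, _ in self.triplets}
        ml_from_triplets = {(m, l) for _, m, l in self.triplets}
        if gm_from_triplets != set(self.gm_edges) or ml_from_triplets != set(self.ml_edges):
            raise ValueError("edges and triplets are inconsistent")
        nodes_from_edges = ({g for g, _ in self.gm_edges}
                            | {m for _, m in self.gm_edges}
                            | {m for m, _ in self.ml_edges}
                            | {l for _, l in self.ml_edges})
        if nodes_from_edges != (self.genes | self.mirnas | self.lncrnas):
            raise ValueError("node sets must be exactly the ids appearing in edges")

    @property
    def n_edges(self) -> int:
        return len(self.gm_edges) + len(self.ml_edges)

    def to_nx(self) -> nx.Graph:
        """Undirected typed graph view (node attribute ``node_class``)."""
        g = nx.Graph()
        for n in self.genes:
            g.add_node(n, node_class="gene")
        for n in self.mirnas:
            g.add_node(n, node_class="miRNA")
        for n in self.lncrnas:
            g.add_node(n, node_class="lncRNA")
        g.add_edges_from(self.gm_edges)
        g.add_edges_from(self.ml_edges)
        return g

    def genes_of_lncrna(self, lncrna: str) -> set[str]:
        return {g for g, _, l in self.triplets if l == lncrna}


@dataclass(frozen=True)
class PairCountRow:
    lncrna_id: str
    n_primary: int    # lncRNA–miRNA edges incident to the lncRNA
    n_secondary: int  # miRNA–gene edges (or genes) reached through those miRNAs
    n_total: int


def build_lmmac(pairs: Sequence[CompetingPair]) -> LMMACNetwork:
    """Expand significant competing pairs into triplets and merge them.

    One triplet per (gene, shared miRNA, lncRNA) combination; edges are the
    deduplicated union over triplets.
    """
    triplets: set[tuple[str, str, str]] = set()
    for cp in pairs:
        if not cp.significant:
            raise ValueError(
                f"pair ({cp.gene_id}, {cp.lncrna_id}) is not flagged significant")
        for m in cp.shared_mirnas:
            triplets.add((cp.gene_id, m, cp.lncrna_id))
    if not triplets:
        logger.warning("build_lmmac: empty input, returning empty network")
        return LMMACNetwork(frozenset(), frozenset(), frozenset(),
                            frozenset(), frozenset(), frozenset())
    gm = frozenset((g, m) for g, m, _ in triplets)
    ml = frozenset((m, l) for _, m, l in triplets)
    net = LMMACNetwork(
        genes=frozenset(g for g, _, _ in triplets),
        mirnas=frozenset(m for _, m, _ in triplets),
        lncrnas=frozenset(l for _, _, l in triplets),
        gm_edges=gm, ml_edges=ml, triplets=frozenset(triplets))
    logger.info("build_lmmac genes=%d mirnas=%d lncrnas=%d edges=%d triplets=%d",
                len(net.genes), len(net.mirnas), len(net.lncrnas),
                net.n_edges, len(net.triplets))
    return net


def count_pairs(net: LMMACNetwork, count_genes: bool = False) -> list[PairCountRow]:
    """Primary (lncRNA–miRNA) and secondary (miRNA–gene) pair counts per lncRNA.

    ``n_secondary`` counts distinct miRNA–gene edges whose miRNA is adjacent
    to the lncRNA; with ``count_genes`` it counts distinct genes instead.
    Rows are sorted by total descending, ties lexicographically.
    """
    if not net.lncrnas:
        raise ValueError("empty network")
    rows: list[PairCountRow] = []
    for l in net.lncrnas:
        adj_mirnas = {m for m, ll in net.ml_edges if ll == l}
        n_primary = len(adj_mirnas)
        reached = [(g, m) for g, m in net.gm_edges if m in adj_mirnas]
        n_secondary = len({g for g, _ in reached}) if count_genes else len(reached)
        rows.append(PairCountRow(lncrna_id=l, n_primary=n_primary,
                                 n_secondary=n_secondary,
                                 n_total=n_primary + n_secondary))
    rows.sort(key=lambda r: (-r.n_total, r.lncrna_id))
    return rows


def write_counts(rows: Sequence[PairCountRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna\tn_primary\tn_secondary\tn_total\n")
        for r in rows:
            fh.write(f"{r.lncrna_id}\t{r.n_primary}\t{r.n_secondary}\t{r.n_total}\n")


def write_lmmac(net: LMMACNetwork, path: str | Path) -> None:
    """GraphML serialization; triplets ride along as a graph attribute."""
    g = net.to_nx()
    g.graph["triplets"] = json.dumps(sorted(net.triplets))
    nx.write_graphml(g, path)


def read_lmmac(path: str | Path) -> LMMACNetwork:
    g = nx.read_graphml(path)
    triplets = frozenset(tuple(t) for t in json.loads(g.graph["triplets"]))
    gm = frozenset((t[0], t[1]) for t in triplets)
    ml = frozenset((t[1], t[2]) for t in triplets)
    return LMMACNetwork(
        genes=frozenset(t[0] for t in triplets),
        mirnas=frozenset(t[1] for t in triplets),
        lncrnas=frozenset(t[2] for t in triplets),
        gm_edges=gm, ml_edges=ml, triplets=triplets)
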