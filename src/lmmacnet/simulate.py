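"""Synthetic inputs with planted signal and known ground truth.

Three generators emulate the statistical structure the pipeline assumes:

* an interactome in which planted gene–lncRNA pairs are wired to the same
  risk miRNAs (competing triplet-families) among Erdős–Rényi decoy edges;
* an expression matrix in which planted pairs are drawn from a bivariate
  normal with a specified correlation and decoys are independent;
* a scored PPI edge list with planted near-clique complexes in a sparse
  background, plus a sub-threshold noise tier to exercise the confidence
  filter.

A designated "signal" lncRNA is additionally wired to the miRNA sets of
enough triplet-families to cover a configurable fraction of the seed
genes; it is the planted positive for the prioritization stage. Every
generator is a pure function of (config, rng_seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, InteractionTable, write_id_list
from .network import LMMACNetwork

logger = logging.getLogger("lmmacnet")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the standard benchmark: 50 genes, 60 miRNAs, 40
    lncRNAs, 5 planted triplet-families sharing 3 risk miRNAs each, decoy
    wiring probability 0.02, planted expression correlation 0.9 over 100
    samples, and three planted PPI complexes of sizes 6/5/4 in a p = 0.03
    background.
    """

    n_genes: int = 50
    n_mirnas: int = 60
    n_lncrnas: int = 40
    n_risk_mirnas: int = 50
    n_planted_triplets: int = 5
    shared_mirnas_per_planted: int = 3
    decoy_edge_prob: float = 0.02
    planted_rho: float = 0.9
    n_samples: int = 100
    ppi_n: int = 50
    ppi_background_p: float = 0.03
    ppi_noise_p: float = 0.03
    planted_clique_sizes: tuple[int, ...] = (6, 5, 4)
    signal_lncrna: bool = True
    signal_coverage: float = 0.6
    lognormal_expression: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not -1.0 < self.planted_rho < 1.0:
            raise ValueError("planted_rho must be in (-1, 1)")
        if not 0.0 <= self.decoy_edge_prob <= 1.0:
            raise ValueError("decoy_edge_prob must be in [0, 1]")
        if self.n_risk_mirnas > self.n_mirnas:
            raise ValueError("n_risk_mirnas exceeds n_mirnas")
        if self.n_planted_triplets * self.shared_mirnas_per_planted > self.n_risk_mirnas:
            raise ValueError("planted families need more risk miRNAs than available")
        if self.n_planted_triplets > min(self.n_genes, self.n_lncrnas):
            raise ValueError("more planted families than genes or lncRNAs")
        if sum(self.planted_clique_sizes) > self.ppi_n:
            raise ValueError("planted cliques exceed PPI size")


@dataclass
class GroundTruth:
    """Planted-signal record consistent with the emitted files."""

    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    signal_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_modules: list[frozenset[str]] = field(default_factory=list)
    planted_lncrna: str | None = None
    seed_genes: tuple[str, ...] = ()
    risk_mirnas: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "planted_pairs": sorted(list(p) for p in self.planted_pairs),
            "planted_triplets": sorted(list(t) for t in self.planted_triplets),
            "signal_pairs": sorted(list(p) for p in self.signal_pairs),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "planted_lncrna": self.planted_lncrna,
            "seed_genes": list(self.seed_genes),
            "risk_mirnas": list(self.risk_mirnas),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_pairs={tuple(p) for p in d["planted_pairs"]},
            planted_triplets={tuple(t) for t in d["planted_triplets"]},
            signal_pairs={tuple(p) for p in d["signal_pairs"]},
            planted_modules=[frozenset(m) for m in d["planted_modules"]],
            planted_lncrna=d["planted_lncrna"],
            seed_genes=tuple(d["seed_genes"]),
            risk_mirnas=tuple(d["risk_mirnas"]),
        )


def gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]


def mirna_ids(cfg: SynthConfig) -> list[str]:
    return [f"MIR{i:04d}" for i in range(1, cfg.n_mirnas + 1)]


def lncrna_ids(cfg: SynthConfig) -> list[str]:
    return [f"LNC{i:04d}" for i in range(1, cfg.n_lncrnas + 1)]


def _clique_gene_blocks(cfg: SynthConfig) -> list[list[str]]:
    # planted complexes occupy consecutive gene-id blocks from the front,
    # so the interactome generator can place its planted genes inside them
    # without needing the PPI truth object
    genes = gene_ids(cfg)
    blocks, start = [], 0
    for size in cfg.planted_clique_sizes:
        blocks.append(genes[start:start + size])
        start += size
    return blocks


def simulate_interactome(cfg: SynthConfig) -> tuple[InteractionTable, InteractionTable, GroundTruth]:
    """miRNA–gene and miRNA–lncRNA tables with planted competing triplets.

    Each triplet-family wires one gene (drawn from the planted PPI-complex
    genes) and one lncRNA to the same disjoint block of
    ``shared_mirnas_per_planted`` risk miRNAs. Decoy edges are added
    independently with ``decoy_edge_prob``.

    When ``signal_lncrna`` is on, the first ceil(signal_coverage *
    families) families are merged into a "signal block": their genes and
    lncRNAs, plus one extra signal lncRNA, are all wired to the union of
    the block's miRNAs. The signal lncRNA therefore competes (with a very
    large shared-miRNA overlap) with genes covering ``signal_coverage`` of
    the seed genes — the planted positive for the prioritization stage.
    The block's cross pairs are genuine planted competition and are
    recorded in ``truth.signal_pairs``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = gene_ids(cfg)
    mirnas = mirna_ids(cfg)
    lncs = lncrna_ids(cfg)
    risk_mirnas = list(rng.choice(mirnas, size=cfg.n_risk_mirnas, replace=False))

    module_genes = [g for block in _clique_gene_blocks(cfg) for g in block]
    pool = module_genes if module_genes else genes
    if cfg.n_planted_triplets > len(pool):
        raise ValueError("not enough planted-module genes for the triplet families")
    fam_genes = list(rng.choice(pool, size=cfg.n_planted_triplets, replace=False))
    fam_lncs = list(rng.choice(lncs, size=cfg.n_planted_triplets + 1, replace=False))
    signal_lnc = fam_lncs.pop() if cfg.signal_lncrna else None
    mirna_pool = list(rng.choice(risk_mirnas,
                                 size=cfg.n_planted_triplets * cfg.shared_mirnas_per_planted,
                                 replace=False))
    k = cfg.shared_mirnas_per_planted
    fam_mirnas = [mirna_pool[i * k:(i + 1) * k] for i in range(cfg.n_planted_triplets)]

    truth = GroundTruth(risk_mirnas=tuple(risk_mirnas),
                        seed_genes=tuple(fam_genes),
                        planted_lncrna=signal_lnc)
    gm: set[tuple[str, str]] = set()
    ml: set[tuple[str, str]] = set()
    for g, l, ms in zip(fam_genes, fam_lncs, fam_mirnas):
        truth.planted_pairs.add((g, l))
        for m in ms:
            truth.planted_triplets.add((g, m, l))
            gm.add((m, g))
            ml.add((m, l))
    if signal_lnc is not None:
        n_cov = int(np.ceil(cfg.signal_coverage * cfg.n_planted_triplets))
        block_genes = fam_genes[:n_cov]
        block_lncs = fam_lncs[:n_cov] + [signal_lnc]
        block_mirnas = sorted({m for ms in fam_mirnas[:n_cov] for m in ms})
        for g in block_genes:
            for m in block_mirnas:
                gm.add((m, g))
            for l in block_lncs:
                if (g, l) not in truth.planted_pairs:
                    truth.signal_pairs.add((g, l))
                for m in block_mirnas:
                    truth.planted_triplets.add((g, m, l))
        for l in block_lncs:
            for m in block_mirnas:
                ml.add((m, l))

    draw_g = rng.random((cfg.n_mirnas, cfg.n_genes)) < cfg.decoy_edge_prob
    draw_l = rng.random((cfg.n_mirnas, cfg.n_lncrnas)) < cfg.decoy_edge_prob
    for i, m in enumerate(mirnas):
        for j, g in enumerate(genes):
            if draw_g[i, j]:
                gm.add((m, g))
        for j, l in enumerate(lncs):
            if draw_l[i, j]:
                ml.add((m, l))

    mg_table = InteractionTable("miRNA", "gene", tuple(sorted(gm)))
    ml_table = InteractionTable("miRNA", "lncRNA", tuple(sorted(ml)))
    _check_truth_consistency(truth, mg_table, ml_table)
    return mg_table, ml_table, truth


def _check_truth_consistency(truth: GroundTruth, mg: InteractionTable,
                             ml: InteractionTable) -> None:
    gm_edges = set(mg.edges)
    ml_edges = set(ml.edges)
    for g, m, l in truth.planted_triplets:
        assert (m, g) in gm_edges and (m, l) in ml_edges, \
            f"planted triplet ({g}, {m}, {l}) missing from emitted tables"


def simulate_expression(cfg: SynthConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Expression with planted correlation structure.

    Transcripts of one triplet-family (its gene, lncRNA, and the signal
    lncRNA when the family is covered) share a latent factor with loading
    sqrt(rho), giving every planted pair a population correlation of
    ``planted_rho``; all other transcripts are independent standard
    normals. Row order is randomized. A log-normal transform is available
    for cosmetic realism (the correlation gate is computed on whatever
    scale the matrix carries, so tests use the normal scale).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    transcripts = gene_ids(cfg) + lncrna_ids(cfg)
    n = cfg.n_samples
    rho = cfg.planted_rho
    values = {t: rng.standard_normal(n) for t in transcripts}

    # group members per latent factor: each planted family forms a group;
    # the signal lncRNA joins every family it covers, so covered families
    # (and the signal) must share ONE factor for all its pairs to reach rho
    covered_families: set[str] = {g for g, _ in truth.signal_pairs}
    groups: list[set[str]] = []
    signal_group: set[str] = set()
    for g, l in sorted(truth.planted_pairs):
        if g in covered_families:
            signal_group.update({g, l})
        else:
            groups.append({g, l})
    if signal_group:
        assert truth.planted_lncrna is not None
        signal_group.add(truth.planted_lncrna)
        groups.append(signal_group)

    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    sign = np.sign(rho) if rho != 0 else 1.0
    for group in groups:
        z = rng.standard_normal(n)
        first = True
        for t in sorted(group):
            load = a if first else sign * a
            values[t] = load * z + b * rng.standard_normal(n)
            first = False

    order = list(transcripts)
    rng.shuffle(order)
    mat = np.vstack([values[t] for t in order])
    if cfg.lognormal_expression:
        mat = np.exp(mat)
    return ExpressionMatrix(
        transcript_ids=tuple(order),
        sample_ids=tuple(f"S{i:03d}" for i in range(1, n + 1)),
        values=mat)


def simulate_ppi(cfg: SynthConfig) -> tuple[list[tuple[str, str, float]], GroundTruth]:
    """Scored PPI edge list with planted near-clique complexes.

    Clique edges carry confidence U[0.7, 1.0]; background edges appear with
    ``ppi_background_p`` and confidence U[0.4, 1.0]; an extra noise tier of
    sub-threshold edges (confidence U[0, 0.4)) with ``ppi_noise_p``
    exercises the confidence filter.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    nodes = gene_ids(cfg)[:cfg.ppi_n]
    blocks = _clique_gene_blocks(cfg)
    truth = GroundTruth(planted_modules=[frozenset(b) for b in blocks])
    clique_edges: set[tuple[str, str]] = set()
    edges: list[tuple[str, str, float]] = []
    for block in blocks:
        for i, u in enumerate(block):
            for v in block[i + 1:]:
                clique_edges.add((u, v))
                edges.append((u, v, float(rng.uniform(0.7, 1.0))))
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if (u, v) in clique_edges:
                continue
            if rng.random() < cfg.ppi_background_p:
                edges.append((u, v, float(rng.uniform(0.4, 1.0))))
            elif rng.random() < cfg.ppi_noise_p:
                edges.append((u, v, float(rng.uniform(0.0, 0.4))))
    edges.sort()
    return edges, truth


def random_lmmac(n_genes: int, n_mirnas: int, n_lncrnas: int,
                 p_gm: float, p_ml: float,
                 rng: np.random.Generator) -> LMMACNetwork:
    """Null tripartite network: random bipartite wiring, triplets formed by
    every (gene, miRNA, lncRNA) path. Used for permutation-calibration
    studies where no signal should exist."""
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    mirnas = [f"MIR{i:04d}" for i in range(1, n_mirnas + 1)]
    lncs = [f"LNC{i:04d}" for i in range(1, n_lncrnas + 1)]
    triplets: set[tuple[str, str, str]] = set()
    gm = rng.random((n_mirnas, n_genes)) < p_gm
    ml = rng.random((n_mirnas, n_lncrnas)) < p_ml
    for i, m in enumerate(mirnas):
        tg = [genes[j] for j in np.flatnonzero(gm[i])]
        tl = [lncs[j] for j in np.flatnonzero(ml[i])]
        for g in tg:
            for l in tl:
                triplets.add((g, m, l))
    if not triplets:
        raise ValueError("null network came out empty; raise the wiring probabilities")
    return LMMACNetwork(
        genes=frozenset(t[0] for t in triplets),
        mirnas=frozenset(t[1] for t in triplets),
        lncrnas=frozenset(t[2] for t in triplets),
        gm_edges=frozenset((t[0], t[1]) for t in triplets),
        ml_edges=frozenset((t[1], t[2]) for t in triplets),
        triplets=frozenset(triplets))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\t" + "\t".join(expr.sample_ids) + "\n")
        for t, row in zip(expr.transcript_ids, expr.values):
            fh.write(t + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in table.edges:
            fh.write(f"{s}\t{t}\n")


def write_scored_edges(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tconfidence\n")
        for u, v, s in edges:
            fh.write(f"{u}\t{v}\t{s!r}\n")


def emit_dataset(cfg: SynthConfig, out_dir: str | Path) -> GroundTruth:
    """Generate and write the complete input set for one pipeline run.

    Emits mirna_gene.tsv, mirna_lncrna.tsv, expr.tsv, ppi_edges.tsv,
    risk_genes.txt, risk_mirnas.txt, seed_genes.txt and truth.json; returns
    the merged ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mg, ml, truth = simulate_interactome(cfg)
    expr = simulate_expression(cfg, truth)
    ppi_edges, ppi_truth = simulate_ppi(cfg)
    truth.planted_modules = ppi_truth.planted_modules
    write_interactions(mg, out / "mirna_gene.tsv")
    write_interactions(ml, out / "mirna_lncrna.tsv")
    write_expression(expr, out / "expr.tsv")
    write_scored_edges(ppi_edges, out / "ppi_edges.tsv")
    write_id_list(gene_ids(cfg)[:cfg.ppi_n], out / "risk_genes.txt")
    write_id_list(truth.risk_mirnas, out / "risk_mirnas.txt")
    write_id_list(truth.seed_genes, out / "seed_genes.txt")
    truth.to_json(out / "truth.json")
    logger.info("emit_dataset out=%s mg_edges=%d ml_edges=%d ppi_edges=%d",
                out, len(mg), len(ml), len(ppi_edges))
    return truth
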