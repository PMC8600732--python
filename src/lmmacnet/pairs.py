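"""Gene–lncRNA competing-pair identification.

A gene and a lncRNA are candidate competitors when they share miRNA
partners; sharing is scored by a hypergeometric test over the risk-miRNA
universe, and surviving pairs must additionally be co-expressed
(Pearson correlation above a floor at a Benjamini–Hochberg FDR ceiling).

Tail convention: the test asks whether the two transcripts share
surprisingly MANY miRNAs, so the default is the upper tail P(X >= x).
The lower-tail cumulative variant that circulates in the ceRNA literature
is kept available as ``tail="lower_as_printed"`` for exact replication of
published pipelines, but it is not a sensible competition test and is not
the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, IdList, InteractionTable

logger = logging.getLogger("lmmacnet")


@dataclass(frozen=True)
class HypergeomInputs:
    """Counts feeding the shared-miRNA test.

    M: size of the risk-miRNA universe; K: miRNAs interacting with the
    gene; N: miRNAs interacting with the lncRNA; x: miRNAs shared by both.
    """

    M: int
    K: int
    N: int
    x: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not (0 <= self.K <= self.M and 0 <= self.N <= self.M):
            raise ValueError("need 0 <= K, N <= M")
        if not 0 <= self.x <= min(self.K, self.N):
            raise ValueError("need 0 <= x <= min(K, N)")


@dataclass(frozen=True)
class CompetingPair:
    gene_id: str
    lncrna_id: str
    shared_mirnas: frozenset[str]
    hyper: HypergeomInputs
    p_hyper: float
    pcc: float | None = None
    p_pcc: float | None = None
    fdr_pcc: float | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        if len(self.shared_mirnas) != self.hyper.x:
            raise ValueError("|shared_mirnas| must equal hyper.x")


def hypergeom_shared_test(h: HypergeomInputs, tail: str = "upper") -> float:
    """Shared-miRNA significance for one gene–lncRNA pair.

    ``upper`` returns P(X >= x) for X ~ Hypergeometric(M, K, N);
    ``lower_as_printed`` returns the cumulative sum
    sum_{i<=x} C(K,i) C(M-K,N-i) / C(M,N).
    """
    if tail == "upper":
        p = float(stats.hypergeom.sf(h.x - 1, h.M, h.K, h.N))
    elif tail == "lower_as_printed":
        p = float(stats.hypergeom.cdf(h.x, h.M, h.K, h.N))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return min(1.0, max(0.0, p))


def candidate_interactions(mirna_gene: InteractionTable,
                           mirna_lncrna: InteractionTable,
                           module_genes: IdList,
                           risk_mirnas: IdList) -> tuple[InteractionTable, InteractionTable]:
    """Restrict raw interaction tables to the disease-relevant candidates.

    miRNA–gene pairs are kept only when the miRNA is a risk miRNA AND the
    gene sits inside a detected module; miRNA–lncRNA pairs only when the
    miRNA is a risk miRNA.
    """
    risk = risk_mirnas.as_set()
    genes = module_genes.as_set()
    mg = mirna_gene.restrict(sources=risk, targets=genes)
    ml = mirna_lncrna.restrict(sources=risk)
    logger.info("candidate_interactions mg_read=%d mg_kept=%d ml_read=%d ml_kept=%d",
                len(mirna_gene), len(mg), len(mirna_lncrna), len(ml))
    if len(mg) == 0 or len(ml) == 0:
        raise ValueError(
            "no candidate interactions left after filtering: "
            f"miRNA-gene {len(mirna_gene)}->{len(mg)}, "
            f"miRNA-lncRNA {len(mirna_lncrna)}->{len(ml)} "
            f"(risk miRNAs: {len(risk)}, module genes: {len(genes)})")
    return mg, ml


def score_all_pairs(mirna_gene: InteractionTable,
                    mirna_lncrna: InteractionTable,
                    risk_mirnas: IdList,
                    p_max: float = 0.01,
                    tail: str = "upper",
                    universe: str = "realized") -> list[CompetingPair]:
    """Hypergeometric stage: test every (gene, lncRNA) pair sharing >= 1 miRNA.

    M is the risk-miRNA universe size: with ``universe="realized"`` (default)
    the risk miRNAs actually present in at least one filtered table, since K
    and N are computed on those tables; ``"curated"`` uses the full risk
    list. Pairs with p below ``p_max`` are returned sorted by p then
    (gene, lncRNA).
    """
    risk = risk_mirnas.as_set()
    if universe == "realized":
        present = (mirna_gene.sources() | mirna_lncrna.sources()) & risk
        M = len(present)
    elif universe == "curated":
        M = len(risk)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if M == 0:
        raise ValueError("empty risk-miRNA universe")
    gene_mirnas = {g: ms & risk for g, ms in mirna_gene.by_target().items()}
    lnc_mirnas = {l: ms & risk for l, ms in mirna_lncrna.by_target().items()}
    out: list[CompetingPair] = []
    n_tested = 0
    for g in sorted(gene_mirnas):
        gm = gene_mirnas[g]
        if not gm:
            continue
        for l in sorted(lnc_mirnas):
            lm = lnc_mirnas[l]
            shared = gm & lm
            if not shared:
                continue
            n_tested += 1
            h = HypergeomInputs(M=M, K=len(gm), N=len(lm), x=len(shared))
            p = hypergeom_shared_test(h, tail=tail)
            if p < p_max:
                out.append(CompetingPair(gene_id=g, lncrna_id=l,
                                         shared_mirnas=frozenset(shared),
                                         hyper=h, p_hyper=p))
    logger.info("score_all_pairs M=%d tested=%d retained=%d", M, n_tested, len(out))
    out.sort(key=lambda cp: (cp.p_hyper, cp.gene_id, cp.lncrna_id))
    return out


def pearson_correlation_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from the exact t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom."""
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up q-values)."""
    return multipletests(list(pvals), method="fdr_bh")[1]


def pearson_with_fdr(pairs: Sequence[CompetingPair],
                     expr: ExpressionMatrix,
                     pcc_min: float = 0.7,
                     fdr_max: float = 0.01,
                     return_all: bool = False) -> list[CompetingPair]:
    """Co-expression gate: annotate each pair with PCC, p and BH-FDR, and
    keep pairs with pcc > ``pcc_min`` AND fdr < ``fdr_max``.

    Pairs with a transcript missing from the matrix, or with a
    zero-variance transcript (correlation undefined), are dropped with a
    log line. With ``return_all`` the full annotated list (significant flag
    set per pair) is returned instead of only the retained pairs.
    """
    present = set(expr.transcript_ids)
    tested: list[CompetingPair] = []
    pvals: list[float] = []
    n_missing = n_degenerate = 0
    for cp in pairs:
        if cp.gene_id not in present or cp.lncrna_id not in present:
            n_missing += 1
            continue
        a = expr.row(cp.gene_id)
        b = expr.row(cp.lncrna_id)
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            n_degenerate += 1
            continue
        r, p = pearson_correlation_p(a, b)
        tested.append(replace(cp, pcc=r, p_pcc=p))
        pvals.append(p)
    if n_missing:
        logger.info("pearson_with_fdr pairs_missing_expression=%d", n_missing)
    if n_degenerate:
        logger.warning("pearson_with_fdr zero_variance_pairs_dropped=%d", n_degenerate)
    if not tested:
        logger.warning("pearson_with_fdr no testable pairs")
        return []
    fdr = bh_fdr(pvals)
    annotated = [
        replace(cp, fdr_pcc=float(q),
                significant=(cp.pcc > pcc_min and float(q) < fdr_max))
        for cp, q in zip(tested, fdr)
    ]
    retained = [cp for cp in annotated if cp.significant]
    logger.info("pearson_with_fdr tested=%d significant=%d", len(annotated), len(retained))
    return annotated if return_all else retained


PAIR_COLUMNS = ("gene", "lncrna", "n_shared", "M", "K", "N", "x",
                "p_hyper", "pcc", "p_pcc", "fdr_pcc", "significant")


def write_pairs(pairs: Sequence[CompetingPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for cp in pairs:
            fh.write("\t".join(str(v) for v in (
                cp.gene_id, cp.lncrna_id, len(cp.shared_mirnas),
                cp.hyper.M, cp.hyper.K, cp.hyper.N, cp.hyper.x,
                repr(cp.p_hyper),
                "" if cp.pcc is None else repr(cp.pcc),
                "" if cp.p_pcc is None else repr(cp.p_pcc),
                "" if cp.fdr_pcc is None else repr(cp.fdr_pcc),
                int(cp.significant))) + "\n")


def write_pairs_with_mirnas(pairs: Sequence[CompetingPair], path) -> None:
    """Pair TSV that also carries the shared miRNA ids (needed to rebuild
    triplets downstream)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS + ("shared_mirnas",)) + "\n")
        for cp in pairs:
            fh.write("\t".join(str(v) for v in (
                cp.gene_id, cp.lncrna_id, len(cp.shared_mirnas),
                cp.hyper.M, cp.hyper.K, cp.hyper.N, cp.hyper.x,
                repr(cp.p_hyper),
                "" if cp.pcc is None else repr(cp.pcc),
                "" if cp.p_pcc is None else repr(cp.p_pcc),
                "" if cp.fdr_pcc is None else repr(cp.fdr_pcc),
                int(cp.significant),
                ",".join(sorted(cp.shared_mirnas)))) + "\n")


def read_pairs_with_mirnas(path) -> list[CompetingPair]:
    out: list[CompetingPair] = []
    with open(path) as fh:
        header = next(fh).rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            h = HypergeomInputs(M=int(f[idx["M"]]), K=int(f[idx["K"]]),
                                N=int(f[idx["N"]]), x=int(f[idx["x"]]))
            out.append(CompetingPair(
                gene_id=f[idx["gene"]], lncrna_id=f[idx["lncrna"]],
                shared_mirnas=frozenset(f[idx["shared_mirnas"]].split(",")),
                hyper=h, p_hyper=float(f[idx["p_hyper"]]),
                pcc=float(f[idx["pcc"]]) if f[idx["pcc"]] else None,
                p_pcc=float(f[idx["p_pcc"]]) if f[idx["p_pcc"]] else None,
                fdr_pcc=float(f[idx["fdr_pcc"]]) if f[idx["fdr_pcc"]] else None,
                significant=bool(int(f[idx["significant"]]))))
    return out
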