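"""Readers, writers and run configuration.

All tabular input is strict TSV: comma-separated files are rejected rather
than delimiter-guessed, because silent guessing corrupts identifiers.
Identifiers are case-sensitive and used verbatim; no alias mapping happens
here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("lmmacnet")

NODE_CLASSES = ("gene", "miRNA", "lncRNA")

#: header tokens recognised during optional-header auto-detection
_HEADER_TOKENS = {
    "source", "source_id", "target", "target_id", "from", "to",
    "mirna", "gene", "lncrna", "evidence", "score", "confidence",
}


class SchemaError(ValueError):
    """A file violated the expected schema (wrong columns, blank id, ...)."""


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated bipartite edge list between two node classes.

    ``edges`` preserves first-occurrence file order; ``evidence`` maps an
    edge to its free-text evidence tag when the source file carried one.
    """

    source_class: str
    target_class: str
    edges: tuple[tuple[str, str], ...]
    evidence: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_class != "miRNA":
            raise SchemaError(f"source_class must be 'miRNA', got {self.source_class!r}")
        if self.target_class not in ("gene", "lncRNA"):
            raise SchemaError(f"target_class must be 'gene' or 'lncRNA', got {self.target_class!r}")
        if len(set(self.edges)) != len(self.edges):
            raise SchemaError("duplicate (source, target) pairs in InteractionTable")
        for s, t in self.edges:
            if not s or not t or s != s.strip() or t != t.strip():
                raise SchemaError(f"blank or untrimmed identifier in edge ({s!r}, {t!r})")

    def __len__(self) -> int:
        return len(self.edges)

    def sources(self) -> set[str]:
        return {s for s, _ in self.edges}

    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def by_target(self) -> dict[str, set[str]]:
        """Map target id -> set of interacting source (miRNA) ids."""
        out: dict[str, set[str]] = {}
        for s, t in self.edges:
            out.setdefault(t, set()).add(s)
        return out

    def restrict(self, sources: set[str] | None = None,
                 targets: set[str] | None = None) -> "InteractionTable":
        kept = tuple(
            (s, t) for s, t in self.edges
            if (sources is None or s in sources) and (targets is None or t in targets)
        )
        ev = {e: self.evidence[e] for e in kept if e in self.evidence}
        return InteractionTable(self.source_class, self.target_class, kept, ev)


def _is_header(fields: Sequence[str]) -> bool:
    return all(f.lower() in _HEADER_TOKENS for f in fields[:2])


def read_interactions(path: str | Path, source_class: str, target_class: str,
                      evidence_whitelist: Sequence[str] | None = None) -> InteractionTable:
    """Read a 2–3 column TSV edge list (source_id, target_id[, evidence]).

    A header row is auto-detected from common column-name tokens. Duplicate
    pairs are collapsed (count logged). ``evidence_whitelist`` optionally
    keeps only rows whose evidence field contains one of the given
    substrings (rows without an evidence field are then dropped) — this
    supports restriction to, e.g., reporter-assay / western-blot support
    without assuming a fixed evidence vocabulary.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    edges: list[tuple[str, str]] = []
    evidence: dict[tuple[str, str], str] = {}
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    n_evidence_dropped = 0
    first_data_line = True
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) == 1 and "," in raw:
            raise SchemaError(
                f"{path}:{lineno}: looks comma-separated; input must be TSV")
        if len(fields) not in (2, 3):
            raise SchemaError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(fields)}")
        fields = [f.strip() for f in fields]
        if first_data_line and _is_header(fields):
            first_data_line = False
            continue
        first_data_line = False
        s, t = fields[0], fields[1]
        if not s or not t:
            raise SchemaError(f"{path}:{lineno}: blank identifier field")
        ev = fields[2] if len(fields) == 3 else None
        if evidence_whitelist is not None:
            if ev is None or not any(w in ev for w in evidence_whitelist):
                n_evidence_dropped += 1
                continue
        if (s, t) in seen:
            n_dup += 1
            continue
        seen.add((s, t))
        edges.append((s, t))
        if ev is not None:
            evidence[(s, t)] = ev
    if not edges:
        raise SchemaError(f"{path}: no interaction rows")
    if n_dup:
        logger.info("read_interactions file=%s duplicates_collapsed=%d", path, n_dup)
    if n_evidence_dropped:
        logger.info("read_interactions file=%s evidence_filtered=%d", path, n_evidence_dropped)
    return InteractionTable(source_class, target_class, tuple(edges), evidence)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Transcripts x samples real matrix; units arbitrary but consistent."""

    transcript_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_transcripts, n_samples)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise SchemaError("expression matrix shape mismatch")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise SchemaError("duplicate transcript ids")
        if len(self.sample_ids) < 3:
            raise SchemaError("need at least 3 samples (correlation undefined below that)")
        if np.isnan(self.values).any():
            raise SchemaError("missing values remain after loading")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, transcript_id: str) -> np.ndarray:
        try:
            i = self._index[transcript_id]
        except AttributeError:
            object.__setattr__(self, "_index",
                               {t: i for i, t in enumerate(self.transcript_ids)})
            i = self._index[transcript_id]
        return self.values[i]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in set(self.transcript_ids)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a transcripts x samples TSV (first column transcript id, header row).

    Rows with any non-numeric or missing cell are dropped and counted in the
    log (no imputation: downstream correlation needs complete pairs).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: need >=3 sample columns, got {df.shape[1]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise SchemaError(f"{path}: duplicate transcript ids {dups[:5]}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        logger.info("read_expression file=%s rows_dropped=%d", path, int(bad.sum()))
        num = num.loc[~bad]
    if num.empty:
        raise SchemaError(f"{path}: no complete numeric rows")
    return ExpressionMatrix(
        transcript_ids=tuple(str(i) for i in num.index),
        sample_ids=tuple(str(c) for c in num.columns),
        values=num.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# id lists and gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdList:
    """Ordered duplicate-free identifier list with a declared role."""

    role: str  # one of {risk_gene, risk_miRNA, seed_gene}
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in ("risk_gene", "risk_miRNA", "seed_gene"):
            raise SchemaError(f"unknown IdList role {self.role!r}")
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("duplicate ids in IdList")
        if not self.ids:
            raise SchemaError("empty IdList")

    def __len__(self) -> int:
        return len(self.ids)

    def as_set(self) -> set[str]:
        return set(self.ids)


def read_id_list(path: str | Path, role: str) -> IdList:
    """One identifier per line; '#' lines are comments; order preserved."""
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    for raw in path.read_text().splitlines():
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        if s not in seen:
            seen.add(s)
            ids.append(s)
    if not ids:
        raise SchemaError(f"{path}: empty id list")
    return IdList(role=role, ids=tuple(ids))


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name TAB description TAB member ids.

    Duplicate members within a set are collapsed; a duplicate set name is a
    hard error; a memberless line yields an empty set with a warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise SchemaError(f"{path}:{lineno}: GMT line needs name and description")
        name = fields[0].strip()
        if name in sets:
            raise SchemaError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        members = {f.strip() for f in fields[2:] if f.strip()}
        if not members:
            logger.warning("read_gmt file=%s set=%s empty", path, name)
        sets[name] = members
    if not sets:
        raise SchemaError(f"{path}: no gene sets")
    return sets


# ---------------------------------------------------------------------------
# typed network export / import
# ---------------------------------------------------------------------------

def write_network(nodes: Iterable[tuple[str, str]], edges: Iterable[tuple[str, str]],
                  path: str | Path, format: str = "tsv") -> None:
    """Write a typed node/edge set as TSV or GraphML.

    TSV layout: source, source_class, target, target_class; an isolated node
    is a row with empty target fields. Reading the file back yields the
    identical node and edge sets.
    """
    nodes = list(nodes)
    edges = list(edges)
    cls = dict(nodes)
    if len(cls) != len(nodes):
        raise SchemaError("duplicate node ids in write_network")
    for c in cls.values():
        if c not in NODE_CLASSES:
            raise SchemaError(f"unknown node class {c!r}")
    for u, v in edges:
        if u not in cls or v not in cls:
            raise SchemaError(f"edge ({u}, {v}) references unknown node")
    path = Path(path)
    if format == "tsv":
        linked = {u for e in edges for u in e}
        with path.open("w") as fh:
            fh.write("source\tsource_class\ttarget\ttarget_class\n")
            for u, v in sorted(edges):
                fh.write(f"{u}\t{cls[u]}\t{v}\t{cls[v]}\n")
            for n in sorted(cls):
                if n not in linked:
                    fh.write(f"{n}\t{cls[n]}\t\t\n")
    elif format == "graphml":
        g = nx.Graph()
        for n, c in nodes:
            g.add_node(n, node_class=c)
        g.add_edges_from(edges)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path, format: str = "tsv") -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Inverse of :func:`write_network`.

    Returns (nodes, edges) with nodes as (id, class) pairs and edges as
    sorted id pairs (the graph is undirected).
    """
    path = Path(path)
    if format == "tsv":
        nodes: set[tuple[str, str]] = set()
        edges: set[tuple[str, str]] = set()
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if lineno == 1 or not raw.strip():
                continue
            f = raw.split("\t")
            if len(f) != 4:
                raise SchemaError(f"{path}:{lineno}: expected 4 columns")
            u, uc, v, vc = f
            nodes.add((u, uc))
            if v:
                nodes.add((v, vc))
                edges.add(tuple(sorted((u, v))))
        return nodes, edges
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = {(str(n), d["node_class"]) for n, d in g.nodes(data=True)}
        edges = {tuple(sorted((str(u), str(v)))) for u, v in g.edges()}
        return nodes, edges
    raise ValueError(f"unknown format {format!r}")


def read_scored_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 3-column TSV of scored undirected edges (u, v, confidence)."""
    path = Path(path)
    out: list[tuple[str, str, float]] = []
    first = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        f = [x.strip() for x in raw.split("\t")]
        if len(f) != 3:
            raise SchemaError(f"{path}:{lineno}: expected 3 columns (u, v, score)")
        if first and _is_header(f):
            first = False
            continue
        first = False
        if not f[0] or not f[1]:
            raise SchemaError(f"{path}:{lineno}: blank identifier")
        try:
            score = float(f[2])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric score {f[2]!r}") from exc
        out.append((f[0], f[1], score))
    if not out:
        raise SchemaError(f"{path}: no edges")
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All thresholds driving the analysis stages.

    Defaults are the standard operating point: STRING-style medium
    confidence 0.4 for the PPI, the canonical MCODE parameter set
    (degree cutoff 2, node score cutoff 0.2, k-core 2, max depth 100),
    hypergeometric p < 0.01 then PCC > 0.7 with BH-FDR < 0.01 for competing
    pairs, restart probability 0.7 for the random walk, and 1000
    degree-preserving seed permutations scored at p < 0.05.
    """

    ppi_min_confidence: float = 0.4
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_kcore: int = 2
    mcode_max_depth: int = 100
    hyper_p_max: float = 0.01
    hyper_tail: str = "upper"  # or "lower_as_printed"
    pcc_min: float = 0.7
    fdr_max: float = 0.01
    rwr_restart: float = 0.7
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 1000
    n_permutations: int = 1000
    perm_p_max: float = 0.05
    min_modules_flag: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ppi_min_confidence <= 1.0:
            raise ValueError("ppi_min_confidence must be in [0, 1]")
        if self.mcode_degree_cutoff < 1:
            raise ValueError("mcode_degree_cutoff must be >= 1")
        if not 0.0 <= self.mcode_node_score_cutoff <= 1.0:
            raise ValueError("mcode_node_score_cutoff must be in [0, 1]")
        if self.mcode_kcore < 2:
            raise ValueError("mcode_kcore must be >= 2")
        if self.mcode_max_depth < 1:
            raise ValueError("mcode_max_depth must be >= 1")
        if self.hyper_tail not in ("upper", "lower_as_printed"):
            raise ValueError("hyper_tail must be 'upper' or 'lower_as_printed'")
        if not 0.0 < self.rwr_restart <= 1.0:
            raise ValueError("rwr_restart must be in (0, 1]")
        if self.rwr_tol <= 0:
            raise ValueError("rwr_tol must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_modules_flag < 1:
            raise ValueError("min_modules_flag must be >= 1")

    @classmethod
    def from_flat_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key: value`` (or ``key = value``) config file.

        Unknown keys are a hard error: every key here is a threshold and a
        silently ignored typo would change the analysis.
        """
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            for sep in (":", "="):
                if sep in s:
                    key, _, val = s.partition(sep)
                    break
            else:
                raise SchemaError(f"{path}:{lineno}: expected 'key: value'")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
            t = types[key]
            if t in ("int", int):
                kwargs[key] = int(val)
            elif t in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_flat_file(self, path: str | Path) -> None:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("".join(line + "\n" for line in lines))
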