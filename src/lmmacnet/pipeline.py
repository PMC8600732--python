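"""End-to-end orchestration: modules -> competing pairs -> network -> ranking.

The pipeline is file-driven: every stage reads the serialized output of its
predecessors and writes its own, so a run can be resumed from any stage and
a rerun with the same config and seed is byte-identical. One YAML config
carries the analysis thresholds, the synthetic-generator settings and the
input paths; flat key:value files are accepted for the threshold block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io, network, pairs, ppi, prioritize, simulate

logger = logging.getLogger("lmmacnet")

STAGES = ("simulate", "ppi", "modules", "candidates", "hyper", "pcc",
          "network", "rwr", "map")


@dataclass
class PipelineConfig:
    run: io.RunConfig = field(default_factory=io.RunConfig)
    synth: simulate.SynthConfig | None = None
    paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "lmmac_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {"run", "synth", "paths", "out_dir"}
        unknown = set(d) - known
        if unknown:
            raise io.SchemaError(f"unknown config sections: {sorted(unknown)}")
        run_kwargs = d.get("run", {}) or {}
        _check_keys(run_kwargs, io.RunConfig, "run")
        synth = None
        if "synth" in d and d["synth"] is not None:
            _check_keys(d["synth"], simulate.SynthConfig, "synth")
            synth_kwargs = dict(d["synth"])
            if "planted_clique_sizes" in synth_kwargs:
                synth_kwargs["planted_clique_sizes"] = tuple(synth_kwargs["planted_clique_sizes"])
            synth = simulate.SynthConfig(**synth_kwargs)
        return cls(run=io.RunConfig(**run_kwargs), synth=synth,
                   paths=dict(d.get("paths", {}) or {}),
                   out_dir=str(d.get("out_dir", "lmmac_out")))


def _check_keys(kwargs: dict, cls, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - valid
    if unknown:
        raise io.SchemaError(f"unknown keys in config section {section!r}: {sorted(unknown)}")


@dataclass
class RunReport:
    """Per-stage counts, config echo and wall-clock times for one run."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    truth_comparison: dict | None = None

    def check_monotone(self) -> None:
        """Every 'kept' count must be <= its corresponding 'read' count."""
        for stage, c in self.counts.items():
            for key, kept in c.items():
                if key.endswith("_kept"):
                    read_key = key[:-5] + "_read"
                    if read_key in c and kept > c[read_key]:
                        raise AssertionError(
                            f"{stage}: {key}={kept} exceeds {read_key}={c[read_key]}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "counts": self.counts, "timings": self.timings,
            "config": self.config, "truth_comparison": self.truth_comparison,
        }, indent=1, default=str))

    def to_text(self) -> str:
        lines = []
        for stage in STAGES:
            if stage not in self.counts:
                continue
            kv = " ".join(f"{k}={v}" for k, v in sorted(self.counts[stage].items()))
            lines.append(f"{stage}: {kv}")
        if self.truth_comparison:
            kv = " ".join(f"{k}={v}" for k, v in sorted(self.truth_comparison.items()))
            lines.append(f"truth: {kv}")
        return "\n".join(lines) + "\n"


def read_ranking(path: str | Path) -> list[prioritize.PermutationResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("lncrna\t") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(prioritize.PermutationResult(
                lncrna_id=f[0], observed_score=float(f[1]), m=int(f[2]),
                n=int(f[3]), p_empirical=float(f[4])))
    return out


def run_pipeline(config: PipelineConfig | str | Path, *,
                 simulate_inputs: bool = False,
                 resume: str | None = None) -> RunReport:
    """Execute (or resume) the full discovery pipeline.

    Stage order: PPI construction, module detection, candidate filtering,
    hypergeometric pair scoring, co-expression gating, network assembly,
    random walk + permutation test, lncRNA-to-module mapping. With
    ``simulate_inputs`` the synthetic generator first writes every input
    into ``<out_dir>/data``. ``resume`` names the first stage to execute;
    earlier stages' outputs must already be on disk.
    """
    cfg = PipelineConfig.from_yaml(config) if not isinstance(config, PipelineConfig) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if resume is not None and resume not in STAGES:
        raise ValueError(f"unknown resume stage {resume!r}; stages: {STAGES}")
    start_at = STAGES.index(resume) if resume else 0

    report = RunReport(config={
        "run": dataclasses.asdict(cfg.run),
        "synth": dataclasses.asdict(cfg.synth) if cfg.synth else None,
        "paths": cfg.paths, "out_dir": cfg.out_dir,
    })
    paths = dict(cfg.paths)

    def active(stage: str) -> bool:
        return STAGES.index(stage) >= start_at

    def timed(stage: str):
        t0 = time.perf_counter()
        return lambda: report.timings.__setitem__(stage, time.perf_counter() - t0)

    try:
        # ------------------------------------------------ simulate
        if simulate_inputs:
            data_dir = out / "data"
            if active("simulate"):
                done = timed("simulate")
                if cfg.synth is None:
                    cfg = dataclasses.replace(cfg, synth=simulate.SynthConfig(
                        rng_seed=cfg.run.rng_seed))
                truth = simulate.emit_dataset(cfg.synth, data_dir)
                report.counts["simulate"] = {
                    "planted_pairs": len(truth.planted_pairs),
                    "planted_triplets": len(truth.planted_triplets),
                    "signal_pairs": len(truth.signal_pairs),
                }
                done()
            for key, name in (("ppi_edges", "ppi_edges.tsv"),
                              ("mirna_gene", "mirna_gene.tsv"),
                              ("mirna_lncrna", "mirna_lncrna.tsv"),
                              ("expr", "expr.tsv"),
                              ("risk_mirnas", "risk_mirnas.txt"),
                              ("seed_genes", "seed_genes.txt")):
                paths[key] = str(data_dir / name)

        # ------------------------------------------------ ppi + modules
        modules_path = out / "modules.tsv"
        if active("modules") or active("ppi"):
            done = timed("modules")
            scored = io.read_scored_edges(paths["ppi_edges"])
            net = ppi.build_ppi(scored, cfg.run.ppi_min_confidence)
            modules = ppi.mcode_find_modules(
                net, degree_cutoff=cfg.run.mcode_degree_cutoff,
                node_score_cutoff=cfg.run.mcode_node_score_cutoff,
                kcore=cfg.run.mcode_kcore, max_depth=cfg.run.mcode_max_depth)
            ppi.write_modules(modules, modules_path)
            report.counts["ppi"] = {"edges_read": len(scored), "edges_kept": net.n_edges}
            report.counts["modules"] = {
                "modules_found": len(modules),
                "genes_in_modules": sum(len(m) for m in modules)}
            done()
        else:
            modules = ppi.read_modules(modules_path)

        # ------------------------------------------------ candidates
        cand_mg_path = out / "candidate_mirna_gene.tsv"
        cand_ml_path = out / "candidate_mirna_lncrna.tsv"
        risk_mirnas = io.read_id_list(paths["risk_mirnas"], "risk_miRNA")
        if active("candidates"):
            done = timed("candidates")
            mg = io.read_interactions(paths["mirna_gene"], "miRNA", "gene")
            ml = io.read_interactions(paths["mirna_lncrna"], "miRNA", "lncRNA")
            module_genes = sorted(set().union(*[m.members for m in modules])) if modules else []
            if not module_genes:
                raise ValueError("no module genes available for candidate filtering")
            cand_mg, cand_ml = pairs.candidate_interactions(
                mg, ml, io.IdList("risk_gene", tuple(module_genes)), risk_mirnas)
            simulate.write_interactions(cand_mg, cand_mg_path)
            simulate.write_interactions(cand_ml, cand_ml_path)
            report.counts["candidates"] = {
                "mg_read": len(mg), "mg_kept": len(cand_mg),
                "ml_read": len(ml), "ml_kept": len(cand_ml)}
            done()
        else:
            cand_mg = io.read_interactions(cand_mg_path, "miRNA", "gene")
            cand_ml = io.read_interactions(cand_ml_path, "miRNA", "lncRNA")

        # ------------------------------------------------ hypergeometric stage
        hyper_path = out / "pairs_hyper.tsv"
        if active("hyper"):
            done = timed("hyper")
            hyper_pairs = pairs.score_all_pairs(
                cand_mg, cand_ml, risk_mirnas,
                p_max=cfg.run.hyper_p_max, tail=cfg.run.hyper_tail)
            pairs.write_pairs_with_mirnas(hyper_pairs, hyper_path)
            report.counts["hyper"] = {"pairs_retained": len(hyper_pairs)}
            done()
        else:
            hyper_pairs = pairs.read_pairs_with_mirnas(hyper_path)

        # ------------------------------------------------ co-expression gate
        pairs_path = out / "pairs_all.tsv"
        if active("pcc"):
            done = timed("pcc")
            expr = io.read_expression(paths["expr"])
            annotated = pairs.pearson_with_fdr(
                hyper_pairs, expr, pcc_min=cfg.run.pcc_min,
                fdr_max=cfg.run.fdr_max, return_all=True)
            pairs.write_pairs_with_mirnas(annotated, pairs_path)
            report.counts["pcc"] = {
                "pairs_read": len(hyper_pairs),
                "pairs_tested": len(annotated),
                "pairs_kept": sum(cp.significant for cp in annotated)}
            done()
        else:
            annotated = pairs.read_pairs_with_mirnas(pairs_path)
        significant = [cp for cp in annotated if cp.significant]

        # ------------------------------------------------ network assembly
        net_path = out / "lmmac.graphml"
        if active("network"):
            done = timed("network")
            lmmac = network.build_lmmac(significant)
            network.write_lmmac(lmmac, net_path)
            if lmmac.lncrnas:
                network.write_counts(network.count_pairs(lmmac), out / "counts.tsv")
            report.counts["network"] = {
                "genes": len(lmmac.genes), "mirnas": len(lmmac.mirnas),
                "lncrnas": len(lmmac.lncrnas), "edges": lmmac.n_edges,
                "triplets": len(lmmac.triplets)}
            done()
        else:
            lmmac = network.read_lmmac(net_path)

        # ------------------------------------------------ rwr + permutations
        ranking_path = out / "ranking.tsv"
        rwr_cfg = prioritize.RWRConfig(r=cfg.run.rwr_restart, tol=cfg.run.rwr_tol,
                                       max_iter=cfg.run.rwr_max_iter)
        seeds = set(io.read_id_list(paths["seed_genes"], "seed_gene").ids)
        if active("rwr"):
            done = timed("rwr")
            rng = np.random.default_rng(cfg.run.rng_seed)
            results = prioritize.permutation_pvalues(
                lmmac, seeds, rwr_cfg, cfg.run.n_permutations, rng)
            prioritize.write_ranking(results, None, ranking_path, rwr_cfg.r)
            report.counts["rwr"] = {
                "lncrnas_scored": len(results),
                "candidates": sum(r.p_empirical < cfg.run.perm_p_max for r in results)}
            done()
        else:
            results = read_ranking(ranking_path)

        # ------------------------------------------------ lncRNA-module map
        if active("map"):
            done = timed("map")
            mapping = prioritize.lncrna_module_map(
                results, lmmac, modules,
                perm_p_max=cfg.run.perm_p_max,
                min_modules_flag=cfg.run.min_modules_flag)
            prioritize.write_ranking(results, mapping, ranking_path, rwr_cfg.r)
            with open(out / "lncrna_modules.tsv", "w") as fh:
                fh.write("lncrna\tmodule_rank\n")
                for l, rank in sorted(mapping.edges):
                    fh.write(f"{l}\t{rank}\n")
            report.counts["map"] = {
                "links": len(mapping.edges), "flagged": len(mapping.flagged)}
            done()
    except Exception as exc:
        # partial outputs stay on disk for debugging
        stage = next((s for s in reversed(STAGES) if s in report.counts), "start")
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    if simulate_inputs:
        truth_file = out / "data" / "truth.json"
        if truth_file.exists():
            truth = simulate.GroundTruth.from_json(truth_file)
            found = {(cp.gene_id, cp.lncrna_id) for cp in significant}
            planted = truth.planted_pairs
            expected = planted | truth.signal_pairs
            report.truth_comparison = {
                "planted_pairs": len(planted),
                "planted_recovered": len(found & planted),
                "decoy_pairs_significant": len(found - expected),
                "signal_lncrna_p": next(
                    (r.p_empirical for r in results
                     if r.lncrna_id == truth.planted_lncrna), None),
            }
    report.check_monotone()
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text())
    return report
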