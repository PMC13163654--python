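"""End-to-end orchestration of the comorbidity analysis stages.

A single config drives: synthetic-data generation, genetic correlation /
MR / colocalization, expression preprocessing, co-expression modules and
preservation, hub screening, enrichment and stratification, and the
kinetic drug simulations.  Stage seeds derive from the global seed by a
stable hash of (seed, stage name), so adding a stage never reshuffles the
others.  Runs are reproducible: same config + seed, same statistics.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, enrichment, expression, genetics, kinetics, synthdata
from . import network as network_mod

__all__ = ["RunConfig", "stage_seed", "run_all", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("genetics", "expression", "coexpr", "network", "enrichment",
          "kinetics")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Pipeline configuration; every stage block optional with defaults."""

    seed: int = 0
    out_dir: str = "comorbidnet_run"
    stages: tuple[str, ...] = STAGES
    mr: dict = field(default_factory=dict)
    ldsc: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    expr: dict = field(default_factory=dict)
    sc: dict = field(default_factory=dict)
    net: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    kin: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = dict(d, stages=tuple(d["stages"]))
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _run_genetics(cfg: RunConfig, out: Path) -> dict:
    seed = stage_seed(cfg.seed, "genetics")
    mr_sc = synthdata.MrScenario(**{**cfg.mr, "seed": seed})
    expo, outc = synthdata.gen_mr_data(mr_sc)
    synthdata.write_gwas_tsv(expo, out / "exposure.tsv")
    synthdata.write_gwas_tsv(outc, out / "outcome.tsv")
    inst = genetics.instruments_from_summaries(expo, outc)
    results = {m: genetics.mr_fit(inst, method=m, seed=seed)
               for m in ("ivw", "weighted_median", "egger")}
    q = genetics.heterogeneity_q(inst)
    presso = genetics.mr_presso(inst, seed=seed)
    loo = genetics.leave_one_out(inst)
    loo.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)

    ldsc_sc = synthdata.LdscScenario(**{**cfg.ldsc, "seed": seed})
    s1, s2 = synthdata.gen_gwas_pair(ldsc_sc)
    rg = genetics.ldsc_rg(s1, s2)

    coloc_sc = synthdata.ColocScenario(**{**cfg.coloc, "seed": seed})
    r1, r2 = synthdata.gen_coloc_region(coloc_sc)
    coloc = genetics.coloc_abf(r1, r2)

    mr_rows = [{"method": m, "or": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p": r.p,
                "egger_intercept_p": r.intercept_p}
               for m, r in results.items()]
    pd.DataFrame(mr_rows).to_csv(out / "mr_results.tsv", sep="\t", index=False)
    return {
        "ivw_or": results["ivw"].odds_ratio,
        "weighted_median_or": results["weighted_median"].odds_ratio,
        "egger_or": results["egger"].odds_ratio,
        "egger_intercept_p": results["egger"].intercept_p,
        "cochran_q": q["Q"], "cochran_q_p": q["p"],
        "presso_global_p": presso["global_p"],
        "loo_all_inside_ci": bool(loo["inside_full_ci"].all()),
        "rg": rg.rg, "rg_se": rg.se,
        "coloc_pp4": coloc.pp4,
    }


def _run_expression_stages(cfg: RunConfig, out: Path) -> tuple[dict, dict]:
    seed = stage_seed(cfg.seed, "expression")
    sc = synthdata.ExprScenario(**{**cfg.expr, "seed": seed})
    bundles = synthdata.gen_expression(sc)
    adjusted = [expression.batch_adjust(b) for b in bundles]
    for i, b in enumerate(adjusted):
        synthdata.write_expression(b, out / f"expr_tissue{i + 1}.tsv",
                                   out / f"traits_tissue{i + 1}.tsv")
    de = expression.diff_expr(adjusted[0])
    de.to_csv(out / "diff_expr_tissue1.tsv", sep="\t", index_label="gene")

    sc_sc = synthdata.ScScenario(**{**cfg.sc, "seed": seed})
    counts, meta, genes = synthdata.gen_single_cell(sc_sc)
    synthdata.write_single_cell(counts, meta, genes, out / "sc_counts.mtx",
                                out / "sc_cells.tsv", out / "sc_genes.tsv")
    summ = expression.sc_expression_summary(
        counts, meta, genes, query_genes=list(sc_sc.target_genes))
    summ.to_csv(out / "sc_summary.tsv", sep="\t", index=False)
    target = summ[(summ.gene == sc_sc.target_genes[0])
                  & (summ.cell_type == sc_sc.target_cell_type)].iloc[0]
    stats = {
        "n_de_genes_padj05": int((de["padj"] < 0.05).sum()),
        "sc_target_frac_expressing": float(target.frac_expressing),
        "sc_target_mean_lognorm": float(target.mean_lognorm),
    }
    return stats, {"bundles": adjusted, "raw": bundles}


def _run_coexpr(cfg: RunConfig, out: Path, bundles) -> tuple[dict, dict]:
    seed = stage_seed(cfg.seed, "coexpr")
    b1, b2 = bundles[0], bundles[1]
    scan = coexpr.soft_threshold_scan(b1)
    scan.table.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False)
    a = coexpr.adjacency(b1, coexpr.DEFAULT_POWER)
    w = coexpr.tom(a)
    modules = coexpr.detect_modules(w, gene_ids=b1.matrix.index)
    modules.rename("module").to_csv(out / "modules.tsv", sep="\t",
                                    index_label="gene")
    eg = coexpr.module_eigengene(b1, modules)
    eg.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
    traits = b1.samples.set_index("sample")[["disease_activity", "crp"]]
    mt = coexpr.module_trait_cor(eg, traits)
    mt.to_csv(out / "module_trait_cor.tsv", sep="\t", index=False)
    pres = coexpr.module_preservation(b1, b2, modules, seed=seed)
    pres.to_csv(out / "module_preservation.tsv", sep="\t", index=False)
    blue = 1
    blue_rows = mt[(mt.module == blue) & (mt.trait == "disease_activity")]
    stats = {
        "scan_max_r2": float(scan.table["r2_signed"].max()),
        "selected_power": scan.selected_power,
        "n_modules": int(modules.max()),
        "blue_size": int((modules == blue).sum()),
        "blue_trait_r": float(blue_rows["r"].iloc[0]),
        "blue_zsummary": float(
            pres.loc[pres.module == blue, "zsummary"].iloc[0]),
    }
    return stats, {"modules": modules}


def _run_network(cfg: RunConfig, out: Path) -> tuple[dict, dict]:
    seed = stage_seed(cfg.seed, "network")
    edges = synthdata.gen_network(**{**cfg.net, "seed": seed})
    synthdata.write_edges(edges, out / "edges.tsv")
    g = network_mod.build_graph(edges)
    table = network_mod.centralities(g)
    table.to_csv(out / "centralities.tsv", sep="\t", index=False)
    hubs = network_mod.select_hubs(table)
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
    return ({"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
             "hubs": list(hubs["node"])},
            {"hubs": hubs})


def _run_enrichment(cfg: RunConfig, out: Path, raw_bundles, adjusted,
                    modules) -> dict:
    seed = stage_seed(cfg.seed, "enrichment")
    truth_modules = raw_bundles[0].truth.get("module_of", modules)
    gene_sets = synthdata.gen_gene_sets(truth_modules,
                                        **{**cfg.enrich, "seed": seed})
    synthdata.write_gmt(gene_sets, out / "gene_sets.gmt")
    name, members = next(iter(gene_sets.items()))
    b1 = adjusted[0]
    scores = enrichment.sample_scores(b1, members)
    scores.to_csv(out / "sample_scores.tsv", sep="\t", index_label="sample")
    diff = enrichment.score_group_diff(
        scores, b1.samples.set_index("sample")["group"], seed=seed)
    gsea = enrichment.gsea_permutation(b1, "disease", members,
                                       n_perm=200, seed=seed)
    b2 = adjusted[1]
    strat = enrichment.stratify(enrichment.sample_scores(b2, members), b2,
                                hub_genes=[])
    strat["subtype_summary"].to_csv(out / "subtype_scores.tsv", sep="\t",
                                    index=False)
    report = {
        "gene_set": name,
        "gsea_es": gsea["es"], "gsea_p": gsea["p_perm"],
        "score_diff_d": diff["d"], "score_diff_p": diff["p_perm"],
        "crp_spearman_r": strat["crp_spearman_r"],
        "crp_spearman_p": strat["crp_spearman_p"],
        "subtype_d": {r["subtype"]: r["d_vs_control"]
                      for _, r in strat["subtype_summary"].iterrows()},
    }
    with open(out / "stratification.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _run_kinetics(cfg: RunConfig, out: Path) -> dict:
    params = kinetics.KineticParams(**cfg.kin) if cfg.kin else kinetics.DEFAULT_PARAMS
    stats = {}
    for name, drug in kinetics.DRUGS.items():
        traj = kinetics.simulate_timecourse(params, drug)
        traj.to_frame().to_csv(out / f"trajectory_{name}.csv", index=False)
        m = kinetics.trajectory_metrics(traj)
        stats[name] = {
            "reduction_at_2h": m["reduction_at"](2.0),
            "max_inhibition": m["max_inhibition"],
            "t_min_pstat3": m["t_min_pstat3"],
            "socs3_peak_time": m["socs3_peak_time"],
            "socs3_peak_height": m["socs3_peak_height"],
        }
        dr = kinetics.dose_response(params, drug)
        dr.to_csv(out / f"dose_response_{name}.csv", index=False)
    return stats


def run_all(config: RunConfig) -> dict:
    """Run every configured stage and return the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages),
                    "statistics": {}}
    stats = report["statistics"]
    expr_ctx = None
    coexpr_ctx = None
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        if stage == "genetics":
            stats["genetics"] = _run_genetics(config, out)
        elif stage == "expression":
            stats["expression"], expr_ctx = _run_expression_stages(config, out)
        elif stage == "coexpr":
            if expr_ctx is None:
                stats["expression"], expr_ctx = _run_expression_stages(config, out)
            stats["coexpr"], coexpr_ctx = _run_coexpr(
                config, out, expr_ctx["bundles"])
        elif stage == "network":
            stats["network"], _ = _run_network(config, out)
        elif stage == "enrichment":
            if expr_ctx is None:
                stats["expression"], expr_ctx = _run_expression_stages(config, out)
            modules = coexpr_ctx["modules"] if coexpr_ctx else None
            stats["enrichment"] = _run_enrichment(
                config, out, expr_ctx["raw"], expr_ctx["bundles"], modules)
        elif stage == "kinetics":
            stats["kinetics"] = _run_kinetics(config, out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
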