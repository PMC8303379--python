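"""End-to-end orchestration: counts -> DEGs -> clusters -> enrichment ->
infiltration -> networks, with per-stage artifacts and a run manifest.

Two standard contrasts are built from the sample metadata, each evaluated
per timepoint:

* ``KO_vs_WT``   — knockout-vehicle over wild-type-vehicle;
* ``HA_vs_vehicle`` — knockout-histamine over knockout-vehicle.

Every stage writes its tables under the output directory even when empty,
and the manifest records the config hash and per-stage row counts so the
bookkeeping numbers (DEG counts, edge counts) are auditable from the run
alone. Runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    ExpressionMatrix,
    ImmLncError,
    SignatureSet,
    log2_cpm,
    cpm,
    read_annotation,
    read_counts,
    read_gmt,
    split_by_biotype,
)
from .de import (
    call_degs,
    circos_export,
    deg_counts,
    estimate_dispersion,
    nb_exact_test,
    overlap_sets,
    tmm_factors,
)
from .enrichment import dotplot_table, ora
from .infiltration import (
    celltype_correlation,
    normalize_scores,
    score_fractions,
    ssgsea_scores,
)
from .network import (
    build_multilayer,
    export_network,
    hub_rank,
    lnc_cell_edges,
    lnc_pc_edges,
)
from .profiles import assign_genes, cluster_summary, enumerate_profiles, profile_significance
from .simulate import (
    COMPARISON_HA,
    COMPARISON_KO,
    SimulationConfig,
    simulate_experiment,
    write_simulated_inputs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, contrasts, and thresholds for one pipeline run.

    Either the four input paths are given, or ``simulate`` holds a
    :class:`SimulationConfig` and the inputs are generated. Shipped
    defaults are the screening thresholds of the analysis this pipeline
    reproduces: DEGs at |log2FC| >= 0.5 and p < 0.05; lncRNA-pcRNA edges
    at |r| > 0.9 and BH p < 0.01; lncRNA-immunocyte edges at |r| > 0.75
    and p < 0.001.
    """

    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    signatures: str | None = None
    pathways: str | None = None  # GMT for enrichment; defaults to signatures
    simulate: SimulationConfig | None = None

    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    use_adjusted: bool = False
    min_cpm: float = 1.0
    min_samples: int = 2

    max_unit_change: int = 2
    n_permutations: int = 1000

    ora_min_term: int = 3
    ora_max_term: int = 500
    ora_padj_max: float = 0.05

    alpha: float = 0.25

    r_min_pc: float = 0.9
    padj_max_pc: float = 0.01
    r_min_cell: float = 0.75
    p_max_cell: float = 0.001
    positive_only: bool = False

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "timepoints" in sim:
                sim["timepoints"] = tuple(sim["timepoints"])
            if "arms" in sim:
                sim["arms"] = tuple(sim["arms"])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        mat, ann, signatures, truth = simulate_experiment(cfg.simulate)
        write_simulated_inputs(outdir / "inputs", mat, ann, signatures, truth)
        pathways = read_gmt(cfg.pathways) if cfg.pathways else signatures
        return mat, ann, signatures, pathways
    for name in ("counts", "metadata", "annotation", "signatures"):
        p = getattr(cfg, name)
        if p is None:
            raise ImmLncError(f"config missing input path: {name}")
        if not Path(p).exists():
            raise ImmLncError(f"input path does not exist: {name} = {p}")
    mat = read_counts(cfg.counts, cfg.metadata)
    ann = read_annotation(cfg.annotation)
    signatures = read_gmt(cfg.signatures)
    pathways = read_gmt(cfg.pathways) if cfg.pathways else signatures
    return mat, ann, signatures, pathways


def _comparisons(mat: ExpressionMatrix) -> dict[str, tuple[dict, dict]]:
    """Available two-group contrasts, keyed by name -> (filter A, filter B)."""
    arms = {s.arm for s in mat.samples}
    out: dict[str, tuple[dict, dict]] = {}
    if {"WT_vehicle", "KO_vehicle"} <= arms:
        out[COMPARISON_KO] = (
            {"genotype": "WT", "treatment": "vehicle"},
            {"genotype": "KO", "treatment": "vehicle"},
        )
    if {"KO_vehicle", "KO_histamine"} <= arms:
        out[COMPARISON_HA] = (
            {"genotype": "KO", "treatment": "vehicle"},
            {"genotype": "KO", "treatment": "histamine"},
        )
    if not out:
        raise ImmLncError("metadata does not contain any supported contrast")
    return out


def deg_summary(called_tables: Mapping[tuple[str, int], pd.DataFrame]) -> pd.DataFrame:
    """Per-(comparison, timepoint) up/down/total counts plus grand totals.

    Grand-total rows (one per comparison, timepoint column = "all") sum
    the per-timepoint counts; n_total = n_up + n_down everywhere.
    """
    if not called_tables:
        raise ImmLncError("no DEG tables given")
    rows = []
    by_comparison: dict[str, list[dict]] = {}
    for (comparison, tp), tab in sorted(called_tables.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        c = deg_counts(tab)
        rows.append({"comparison": comparison, "timepoint_days": tp, **c})
        by_comparison.setdefault(comparison, []).append(c)
    for comparison, counts in by_comparison.items():
        n_up = sum(c["n_up"] for c in counts)
        n_down = sum(c["n_down"] for c in counts)
        rows.append(
            {
                "comparison": comparison,
                "timepoint_days": "all",
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # ---- inputs ----------------------------------------------------------
    rec = stage("inputs")
    mat, annotation, signatures, pathways = _load_inputs(cfg, outdir)
    rec.update(n_genes=mat.n_genes, n_samples=mat.n_samples, n_signatures=len(signatures))

    factors = tmm_factors(mat)
    logcpm = log2_cpm(mat, norm_factors=factors)
    expressed = (cpm(mat) > cfg.min_cpm).sum(axis=1) >= cfg.min_samples
    universe = mat.counts.index[expressed].tolist()
    timepoints = sorted({s.timepoint_days for s in mat.samples})

    # ---- differential expression ----------------------------------------
    rec = stage("differential_expression")
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    called_tables: dict[tuple[str, int], pd.DataFrame] = {}
    for comparison, (filt_a, filt_b) in _comparisons(mat).items():
        for tp in timepoints:
            group_a = mat.which_samples(timepoint_days=tp, **filt_a)
            group_b = mat.which_samples(timepoint_days=tp, **filt_b)
            if not group_a or not group_b:
                continue
            res = nb_exact_test(
                mat,
                group_a,
                group_b,
                norm_factors=factors[group_a + group_b],
                min_cpm=cfg.min_cpm,
                min_samples=cfg.min_samples,
                comparison=comparison,
                timepoint_days=tp,
            )
            called = call_degs(
                res,
                lfc_threshold=cfg.lfc_threshold,
                p_threshold=cfg.p_threshold,
                use_adjusted=cfg.use_adjusted,
            )
            called.to_csv(de_dir / f"{comparison}_day{tp}.tsv", sep="\t", index=False)
            called_tables[(comparison, tp)] = called
            rec[f"{comparison}_day{tp}"] = deg_counts(called)

    summary = deg_summary(called_tables)
    summary.to_csv(de_dir / "deg_summary.tsv", sep="\t", index=False)

    # Venn regions: per comparison across timepoints, plus cross-comparison
    # overlap at each shared timepoint
    deg_ids = {
        key: set(tab.loc[tab["direction"] != "ns", "gene_id"])
        for key, tab in called_tables.items()
    }
    venn: dict[str, list] = {}
    comparisons = sorted({c for c, _ in called_tables})
    for comparison in comparisons:
        named = {
            f"day{tp}": deg_ids[(comparison, tp)]
            for tp in timepoints
            if (comparison, tp) in deg_ids
        }
        if len(named) >= 2:
            venn[comparison] = overlap_sets(named).to_dict(orient="records")
    if len(comparisons) == 2:
        for tp in timepoints:
            keys = [(c, tp) for c in comparisons if (c, tp) in deg_ids]
            if len(keys) == 2:
                venn[f"day{tp}_across_comparisons"] = overlap_sets(
                    {c: deg_ids[(c, tp)] for c, _ in keys}
                ).to_dict(orient="records")
    (de_dir / "venn.json").write_text(json.dumps(venn, indent=1, default=str))

    for comparison in comparisons:
        tabs = {tp: called_tables[(comparison, tp)] for tp in timepoints
                if (comparison, tp) in called_tables}
        circos = circos_export(tabs, annotation)
        circos.to_csv(de_dir / f"circos_{comparison}.tsv", sep="\t", index=False)
        rec[f"circos_{comparison}_rows"] = len(circos)

    # ---- temporal clustering --------------------------------------------
    rec = stage("temporal_clustering")
    cl_dir = outdir / "clusters"
    cl_dir.mkdir(exist_ok=True)
    profiles_all = enumerate_profiles(len(timepoints), cfg.max_unit_change)
    for comparison, (filt_a, filt_b) in _comparisons(mat).items():
        union: set[str] = set()
        for tp in timepoints:
            union |= deg_ids.get((comparison, tp), set())
        if not union:
            for suffix in ("profiles", "members", "summary"):
                pd.DataFrame().to_csv(cl_dir / f"{comparison}_{suffix}.tsv", sep="\t")
            rec[comparison] = {"n_genes": 0}
            continue
        arm_means = {}
        for tp in timepoints:
            ids = mat.which_samples(timepoint_days=tp, **filt_b)
            arm_means[tp] = logcpm.loc[sorted(union), ids].mean(axis=1)
        traj = pd.DataFrame(arm_means)
        traj = traj.sub(traj.iloc[:, 0], axis=0)
        profiles = enumerate_profiles(len(timepoints), cfg.max_unit_change)
        assignment = assign_genes(traj, profiles)
        sig = profile_significance(
            traj, profiles, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        summary_df, members = cluster_summary(assignment, traj, profiles)
        sig.to_csv(cl_dir / f"{comparison}_profiles.tsv", sep="\t", index=False)
        members.to_csv(cl_dir / f"{comparison}_members.tsv", sep="\t", index=False)
        summary_df.to_csv(cl_dir / f"{comparison}_summary.tsv", sep="\t", index=False)
        rec[comparison] = {
            "n_genes": len(traj),
            "n_significant_profiles": int(sig["significant"].sum()),
        }

    # ---- enrichment ------------------------------------------------------
    rec = stage("enrichment")
    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    enr_results: dict[str, pd.DataFrame] = {}
    for (comparison, tp), ids in deg_ids.items():
        label = f"{comparison}_day{tp}"
        if not ids:
            pd.DataFrame().to_csv(enr_dir / f"{label}.tsv", sep="\t")
            continue
        query = [g for g in ids if g in universe]
        if not query:
            pd.DataFrame().to_csv(enr_dir / f"{label}.tsv", sep="\t")
            continue
        res = ora(
            query, universe, pathways,
            min_term=cfg.ora_min_term, max_term=cfg.ora_max_term,
        )
        res.to_csv(enr_dir / f"{label}.tsv", sep="\t", index=False)
        enr_results[label] = res
        rec[label] = {
            "n_terms_tested": len(res),
            "n_significant": int((res["p_adjusted"] < cfg.ora_padj_max).sum())
            if not res.empty
            else 0,
        }
    if enr_results:
        dotplot_table(enr_results).to_csv(enr_dir / "dotplot.tsv", sep="\t", index=False)

    # ---- immune infiltration --------------------------------------------
    rec = stage("infiltration")
    inf_dir = outdir / "infiltration"
    inf_dir.mkdir(exist_ok=True)
    raw_es = ssgsea_scores(logcpm, signatures, alpha=cfg.alpha)
    norm = normalize_scores(raw_es)
    fractions = score_fractions(norm)
    corr_r, corr_p = celltype_correlation(norm)
    raw_es.to_csv(inf_dir / "raw_es.tsv", sep="\t")
    norm.to_csv(inf_dir / "normalized.tsv", sep="\t")
    fractions.to_csv(inf_dir / "fractions.tsv", sep="\t")
    corr_r.to_csv(inf_dir / "celltype_correlation_r.tsv", sep="\t")
    corr_p.to_csv(inf_dir / "celltype_correlation_p.tsv", sep="\t")
    rec.update(n_celltypes=raw_es.shape[0], n_samples=raw_es.shape[1])

    # ---- network ---------------------------------------------------------
    rec = stage("network")
    net_dir = outdir / "network"
    net_dir.mkdir(exist_ok=True)
    pc_mat, lnc_mat = split_by_biotype(mat, annotation)
    pc_expr = logcpm.loc[[g for g in pc_mat.gene_ids if g in universe]]
    lnc_expr = logcpm.loc[[g for g in lnc_mat.gene_ids if g in universe]]
    if lnc_expr.empty or pc_expr.empty:
        raise ImmLncError("network stage needs expressed genes of both biotypes")
    pc_edges = lnc_pc_edges(
        lnc_expr, pc_expr,
        r_min=cfg.r_min_pc, padj_max=cfg.padj_max_pc, positive_only=cfg.positive_only,
    )
    cell_edges = lnc_cell_edges(
        lnc_expr, norm,
        r_min=cfg.r_min_cell, p_max=cfg.p_max_cell, positive_only=cfg.positive_only,
    )
    pc_edges.to_csv(net_dir / "lnc_pc_edges.tsv", sep="\t", index=False)
    cell_edges.to_csv(net_dir / "lnc_cell_edges.tsv", sep="\t", index=False)
    all_edges = pd.concat([pc_edges, cell_edges], ignore_index=True)
    if not all_edges.empty:
        hubs = hub_rank(all_edges)
    else:
        hubs = pd.DataFrame(columns=["lncRNA", "degree", "category"])
    hubs.to_csv(net_dir / "hubs.tsv", sep="\t", index=False)

    net = build_multilayer(
        cell_edges, pc_edges, pathways, universe,
        ora_padj_max=cfg.ora_padj_max,
        min_term=cfg.ora_min_term, max_term=cfg.ora_max_term,
    )
    export_network(net, "graphml", net_dir / "multilayer.graphml")
    export_network(net, "edgelist", net_dir / "edges.tsv")
    export_network(net, "sankey", net_dir / "sankey.tsv")
    rec.update(
        n_pc_edges=len(pc_edges),
        n_cell_edges=len(cell_edges),
        n_imm_lncrnas=len(net.imm_lncrnas),
        n_go_edges=len(net.go_edges),
    )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
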