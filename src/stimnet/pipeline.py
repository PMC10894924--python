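"""End-to-end orchestration of the stimulation-response network pipeline.

Stages run in the study's order — simulate (optional) → preprocess →
response → differential → modules → enrichment → Bayesian network → GRN →
TF activity → hubs → drug screen — each writing its table plus a JSON
provenance record (parameters, seed, runtime) into the artifact directory,
so any stage's output can be consumed standalone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    bayesnet,
    coexpression,
    connectivity,
    differential,
    enrichment,
    grn,
    hubs,
    io_formats,
    preprocess,
    synthetic,
    tf_activity,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds with their study defaults, plus paths."""

    out_dir: str = "stimnet_out"
    simulate: bool = True
    seed: int = 0
    # input paths (used when simulate is False)
    baseline_path: str | None = None
    stimulated_path: str | None = None
    sidecar_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    tf_list_path: str | None = None
    drug_library_path: str | None = None
    # QC
    min_detected: int = 9000
    min_log2: float = 7.5
    min_sd: float = 0.5
    outlier_k: float = 3.0
    # differential
    lfc_cutoff: float = 1.0
    de_padj_cutoff: float = 0.01
    # co-expression
    power: int = 5
    cut_height: float = 0.995
    min_module_size: int = 50
    merge_height: float = 0.2
    # Bayesian network
    bn_iterations: int = 1000
    genes_per_module: int = 20
    trait: str = "dbp"
    # GRN
    grn_bootstraps: int = 100
    mi_floor: float = 0.5
    dpi_tolerance: float = 0.0
    # hubs
    weight_cutoff: float = 0.4
    hub_alpha: float = 0.05
    # screen
    score_cutoff: float = 0.7
    screen_padj_cutoff: float = 0.05
    screen_permutations: int = 1000
    cell_lines: tuple[str, ...] = synthetic.MYELOID_CELL_LINES
    # trait group comparison
    dbp_cutoff: float = 80.0
    sbp_cutoff: float = 130.0
    # simulation
    sim: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = synthetic.SimulationConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        d["sim"]["module_sizes"] = list(self.sim.module_sizes)
        return d


class StageError(RuntimeError):
    pass


def _provenance(out: Path, stage: str, params: dict, started: float) -> None:
    record = {
        "stage": stage,
        "parameters": params,
        "runtime_s": round(time.time() - started, 3),
    }
    with open(out / f"{stage}.provenance.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, default=str)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts keyed by stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    artifacts: dict = {}
    stage = "setup"
    try:
        # ----- inputs ------------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            baseline, stimulated, clin, truth = synthetic.simulate_cohort(sim_cfg)
            library = synthetic.simulate_drug_library(
                sim_cfg, truth, n_landmark=min(978, sim_cfg.n_genes))
            collection = synthetic.simulate_gene_sets(truth, seed=cfg.seed + 1)
            tf_list = list(truth.regulons)
            io_formats.write_expression_matrix(
                baseline, out / "baseline.tsv", out / "samples.tsv")
            io_formats.write_expression_matrix(stimulated, out / "stimulated.tsv")
            io_formats.write_clinical_table(clin, out / "clinical.tsv")
            io_formats.write_drug_library(library, out / "drug_library.tsv")
            io_formats.write_gmt(collection, out / "gene_sets.gmt")
            truth.to_json(out / "ground_truth.json")
            artifacts["truth"] = truth
            _provenance(out, stage, {"seed": cfg.seed}, t0)
        else:
            required = {
                "baseline_path": cfg.baseline_path,
                "stimulated_path": cfg.stimulated_path,
                "clinical_path": cfg.clinical_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise StageError(f"missing required inputs: {missing}")
            baseline = io_formats.read_expression_matrix(
                cfg.baseline_path, cfg.sidecar_path)
            stimulated = io_formats.read_expression_matrix(
                cfg.stimulated_path, cfg.sidecar_path)
            clin = io_formats.read_clinical_table(cfg.clinical_path)
            collection = (io_formats.read_gmt(cfg.gmt_path)
                          if cfg.gmt_path else None)
            tf_list = (io_formats.read_tf_list(cfg.tf_list_path)
                       if cfg.tf_list_path else [])
            library = (io_formats.read_drug_library(cfg.drug_library_path)
                       if cfg.drug_library_path else None)
        artifacts["cohort_summary"] = io_formats.summarize_cohort(clin)
        artifacts["clinical"] = clin

        # ----- preprocess --------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        both = _concat(baseline, stimulated)
        filtered, gene_report = preprocess.filter_genes(
            both, cfg.min_log2, cfg.min_sd)
        baseline_f = filtered.subset_samples(filtered.samples_for("baseline"))
        stimulated_f = filtered.subset_samples(filtered.samples_for("stimulated"))
        resp, pair_report = preprocess.build_response_matrix(baseline_f, stimulated_f)
        resp, outlier_report = preprocess.detect_outliers(resp, cfg.outlier_k)
        qc = {
            "genes": gene_report.to_dict(),
            "pairing": pair_report.to_dict(),
            "outliers": outlier_report.to_dict(),
        }
        with open(out / "qc_report.json", "w", encoding="utf-8") as fh:
            json.dump(qc, fh, indent=2)
        resp.log2fc.to_csv(out / "response_matrix.tsv", sep="\t",
                           float_format="%.10g")
        artifacts["response"] = resp
        _provenance(out, stage, {"min_log2": cfg.min_log2, "min_sd": cfg.min_sd,
                                 "outlier_k": cfg.outlier_k}, t0)

        # ----- differential ------------------------------------------------
        stage = "de"
        t0 = time.time()
        de = differential.moderated_de(resp, lfc_cutoff=cfg.lfc_cutoff,
                                       padj_cutoff=cfg.de_padj_cutoff)
        de.table.to_csv(out / "differential_response.tsv", sep="\t",
                        float_format="%.6g")
        artifacts["de"] = de
        _provenance(out, stage, {"lfc_cutoff": cfg.lfc_cutoff,
                                 "padj_cutoff": cfg.de_padj_cutoff}, t0)

        # ----- modules -----------------------------------------------------
        stage = "modules"
        t0 = time.time()
        adj = coexpression.soft_adjacency(resp, power=cfg.power)
        tom_diss = coexpression.topological_overlap(adj)
        partition, eigen = coexpression.detect_modules(
            tom_diss, resp, cut_height=cfg.cut_height,
            min_size=cfg.min_module_size, merge_height=cfg.merge_height)
        pd.Series(partition.labels, name="module").rename_axis("gene").to_csv(
            out / "module_labels.tsv", sep="\t")
        eigen.values.to_csv(out / "eigengenes.tsv", sep="\t", float_format="%.6g")
        mt = coexpression.module_trait_matrix(eigen, clin)
        mt.to_csv(out / "module_trait.tsv", sep="\t", index=False,
                  float_format="%.6g")
        artifacts.update(adjacency=adj, partition=partition, eigengenes=eigen,
                         module_trait=mt)
        _provenance(out, stage, {"power": cfg.power, "cut_height": cfg.cut_height,
                                 "min_size": cfg.min_module_size,
                                 "merge_height": cfg.merge_height}, t0)

        # ----- enrichment --------------------------------------------------
        stage = "enrich"
        t0 = time.time()
        background = set(resp.gene_ids)
        enriched_modules = []
        if collection is not None and partition.modules:
            tables = []
            for module in partition.modules:
                res = enrichment.overrepresentation(
                    set(partition.genes_in(module)), de, collection, background)
                res.table.insert(0, "module", module)
                tables.append(res.table)
                if (res.table["padj"] < 0.05).any():
                    enriched_modules.append(module)
            enr = pd.concat(tables, ignore_index=True)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
            artifacts["enrichment"] = enr
        else:
            enriched_modules = partition.modules
        _provenance(out, stage, {"n_enriched_modules": len(enriched_modules)}, t0)

        # ----- Bayesian network -------------------------------------------
        stage = "bn"
        t0 = time.time()
        bn_labels = partition
        if enriched_modules and set(enriched_modules) != set(partition.modules):
            bn_labels = coexpression.ModulePartition({
                g: (m if m in set(enriched_modules) else coexpression.UNASSIGNED)
                for g, m in partition.labels.items()
            })
        consensus = bayesnet.bootstrap_consensus(
            resp, bn_labels, clin, trait=cfg.trait, n_iter=cfg.bn_iterations,
            genes_per_module=cfg.genes_per_module, seed=cfg.seed)
        with open(out / "consensus_bn.json", "w", encoding="utf-8") as fh:
            json.dump(consensus.to_dict(), fh, indent=2)
        io_formats.write_edge_table(consensus.to_graph(), out / "consensus_bn.sif",
                                    dialect="sif")
        artifacts["bn"] = consensus
        _provenance(out, stage, {"iterations": cfg.bn_iterations,
                                 "genes_per_module": cfg.genes_per_module}, t0)

        # ----- GRN ---------------------------------------------------------
        stage = "grn"
        t0 = time.time()
        regulons = None
        if tf_list:
            regulons = grn.aracne_network(
                resp, tf_list, n_boot=cfg.grn_bootstraps, mi_floor=cfg.mi_floor,
                dpi_tolerance=cfg.dpi_tolerance, seed=cfg.seed)
            regulons = grn.mode_of_regulation(regulons, resp)
            regulons.table.to_csv(out / "regulons.tsv", sep="\t", index=False,
                                  float_format="%.6g")
            artifacts["regulons"] = regulons
        _provenance(out, stage, {"bootstraps": cfg.grn_bootstraps,
                                 "mi_floor": cfg.mi_floor}, t0)

        # ----- TF activity -------------------------------------------------
        stage = "activity"
        t0 = time.time()
        if regulons is not None and not regulons.table.empty:
            sig = tf_activity.rank_signature(resp)
            act = tf_activity.regulon_enrichment(sig, regulons)
            act.nes.to_csv(out / "tf_activity.tsv", sep="\t", float_format="%.6g")
            cor = tf_activity.tf_trait_correlation(act, clin, trait=cfg.trait)
            cor.to_csv(out / "tf_trait_correlation.tsv", sep="\t", index=False,
                       float_format="%.6g")
            artifacts["tf_activity"] = act
        _provenance(out, stage, {}, t0)

        # ----- hubs --------------------------------------------------------
        stage = "hubs"
        t0 = time.time()
        focus = _trait_module(artifacts.get("module_trait"), cfg.trait,
                              partition.modules)
        hub_rep = None
        if focus is not None:
            hub_rep, subnet = hubs.hub_report(
                adj, partition, focus, weight_cutoff=cfg.weight_cutoff,
                alpha=cfg.hub_alpha)
            hub_rep.table.to_csv(out / f"hubs_{focus}.tsv", sep="\t",
                                 float_format="%.6g")
            io_formats.write_edge_table(subnet, out / f"subnetwork_{focus}.tsv")
            artifacts.update(hub_module=focus, hubs=hub_rep)
        _provenance(out, stage, {"module": focus,
                                 "weight_cutoff": cfg.weight_cutoff}, t0)

        # ----- screen ------------------------------------------------------
        stage = "screen"
        t0 = time.time()
        if (library is not None and hub_rep is not None
                and hub_rep.hub_genes):
            hub_response = de.table.loc[hub_rep.hub_genes, "mean_log2fc"]
            report = connectivity.drug_screen(
                hub_response, library, cell_line_filter=list(cfg.cell_lines),
                n_perm=cfg.screen_permutations, score_cutoff=cfg.score_cutoff,
                padj_cutoff=cfg.screen_padj_cutoff, seed=cfg.seed)
            report.table.to_csv(out / "drug_screen.tsv", sep="\t",
                                float_format="%.6g")
            artifacts["screen"] = report
        _provenance(out, stage, {"n_perm": cfg.screen_permutations}, t0)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts


def _concat(baseline: io_formats.ExpressionMatrix,
            stimulated: io_formats.ExpressionMatrix) -> io_formats.ExpressionMatrix:
    values = pd.concat([baseline.values, stimulated.values], axis=1)
    condition = {**baseline.condition, **stimulated.condition}
    patient = {**baseline.patient_id, **stimulated.patient_id}
    return io_formats.ExpressionMatrix(values, condition, patient)


def _trait_module(module_trait: pd.DataFrame | None, trait: str,
                  modules: list[str]) -> str | None:
    """Module most associated with the trait (smallest p, then largest |r|)."""
    if module_trait is None or not modules:
        return modules[0] if modules else None
    sub = module_trait[(module_trait["covariate"] == trait)
                       & module_trait["p"].notna()]
    if sub.empty:
        return modules[0]
    sub = sub.assign(abs_r=sub["r"].abs()).sort_values(
        ["p", "abs_r"], ascending=[True, False])
    return str(sub.iloc[0]["feature"])
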