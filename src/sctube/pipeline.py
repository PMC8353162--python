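"""End-to-end orchestration: QC -> scoring -> classification -> comparisons
-> dynamics -> double-positive analysis, with a machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    binarize_expression,
    two_step_classify,
    write_assignment_tsv,
)
from .compare import staging_correlation
from .config import PipelineConfig
from .counts_io import (
    compute_qc,
    filter_cells,
    infer_sex,
    read_counts,
    write_counts,
)
from .dp import default_gene_space, dp_ratio, dp_similarity, gate_cells
from .dynamics import composition_table, group_territories, neurogenesis_rate
from .knowledge import (
    KnowledgeMatrix,
    default_knowledge_matrix,
    default_tissue_modules,
    load_modules_tsv,
)
from .scoring import (
    default_cell_cycle_modules_safe,
    normalize_log,
    score_modules,
    write_scores_tsv,
)
from .simulate import (
    SimulationParams,
    concat_datasets,
    default_timecourse_preset,
    simulate_bulk_timecourse,
    simulate_timecourse,
    varying_genes,
)

logger = logging.getLogger(__name__)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every non-skipped stage; returns the run report (also written
    as ``report.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger("sctube").addHandler(log_handler)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}, "config": config.to_dict()}
    t0 = time.time()

    def record(stage: str, **info) -> None:
        info["elapsed_s"] = round(time.time() - t0, 3)
        report["stages"][stage] = info
        logger.info("stage %s done: %s", stage, info)

    km = (
        KnowledgeMatrix.from_tsv(config.knowledge_matrix)
        if config.knowledge_matrix
        else default_knowledge_matrix()
    )
    modules = load_modules_tsv(config.modules) if config.modules else default_tissue_modules()

    # --- input: read or simulate --------------------------------------
    truth = None
    if config.counts is not None:
        cm = read_counts(config.counts, config.counts_format)
        record("input", n_cells=cm.shape[1], n_genes=cm.shape[0], source=str(config.counts))
    else:
        if "simulate" in config.skip:
            raise ValueError("no counts path given and the simulate stage is skipped")
        params = SimulationParams(seed=config.stage_seed("simulate"))
        stages = default_timecourse_preset(km, n_cells=config.n_cells_per_stage)
        cm, truth = concat_datasets(simulate_timecourse(stages, params, km))
        write_counts(cm, outdir / "counts")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        record("simulate", n_cells=cm.shape[1], n_genes=cm.shape[0], stages=len(stages))

    # --- QC ------------------------------------------------------------
    if "qc" not in config.skip:
        metrics = compute_qc(cm, config.mito_prefix)
        cm, kept, qc_report = filter_cells(cm, metrics, config.resolved_qc())
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        try:
            sex = infer_sex(cm)
            sex.to_csv(outdir / "sample_sex.tsv", sep="\t")
        except KeyError:
            sex = None
        record("qc", n_kept=len(kept), removed=int(qc_report["n_removed"].iloc[-1]))

    # --- scoring --------------------------------------------------------
    nm = normalize_log(cm)
    if "score" not in config.skip:
        seed = config.stage_seed("score")
        scores = score_modules(nm, modules, n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=seed)
        cc = default_cell_cycle_modules_safe(nm, seed=seed, n_bins=config.n_bins, n_ctrl=config.n_ctrl)
        if cc is not None:
            scores = pd.concat([scores, cc], axis=1)
        write_scores_tsv(scores, outdir / "module_scores.tsv")
        record("score", n_modules=scores.shape[1])

    # --- classification -------------------------------------------------
    assignment, clog = two_step_classify(
        cm,
        km,
        modules,
        min_score=config.min_score,
        max_mismatch=config.max_mismatch,
        binarize_method=config.binarize_method,
        n_bins=config.n_bins,
        n_ctrl=config.n_ctrl,
        seed=config.stage_seed("classify"),
    )
    assignment["stage"] = cm.cell_meta["stage"] if "stage" in cm.cell_meta else "all"
    write_assignment_tsv(assignment, outdir / "assignment.tsv")
    info = dict(clog)
    if truth is not None:
        neural = truth.loc[assignment.index, "truth_tissue"] == "neural"
        match = (
            assignment.loc[neural.to_numpy(), "subtype"]
            == truth.loc[assignment.index[neural.to_numpy()], "truth_type"]
        )
        info["truth_subtype_recovery"] = round(float(match.mean()), 4)
    record("classify", **{k: v for k, v in info.items() if not isinstance(v, dict)})

    # --- comparisons ----------------------------------------------------
    if "compare" not in config.skip:
        ventral = ["p0", "p1", "p2", "pMN", "p3", "V0", "V1", "V2", "MN", "V3"]
        vcells = assignment.index[assignment["subtype"].isin(ventral)]
        if len(vcells) >= config.min_cells:
            nm_v = nm.subset_cells(vcells)
            stage_labels = assignment.loc[vcells, "stage"]
            pseudo = {}
            for stage in pd.unique(stage_labels):
                idx = nm_v.cells[(stage_labels == stage).to_numpy()]
                pseudo[stage] = nm_v.subset_cells(idx).values.mean(axis=1)
            pseudobulk = pd.DataFrame(pseudo, index=nm_v.genes)
            if config.bulk_timecourse:
                bulk = pd.read_csv(config.bulk_timecourse, sep="\t", index_col=0)
            else:
                bulk = simulate_bulk_timecourse(
                    km, None, n_days=pseudobulk.shape[1] + 2,
                    params=SimulationParams(seed=config.stage_seed("compare")),
                )
            genes = [g for g in varying_genes(km) if g in bulk.index]
            stag = staging_correlation(pseudobulk, bulk, genes)
            stag.to_csv(outdir / "staging_correlation.tsv", sep="\t")
            record("compare", n_stages=stag.shape[0], n_days=stag.shape[1])
        else:
            record("compare", skipped="too few ventral cells")

    # --- dynamics -------------------------------------------------------
    if "dynamics" not in config.skip:
        comp = composition_table(assignment[assignment["tissue"] == "neural"])
        comp.counts.to_csv(outdir / "composition_counts.tsv", sep="\t")
        comp.proportions.to_csv(outdir / "composition_proportions.tsv", sep="\t")
        terr = group_territories(assignment, km)
        terr.counts.to_csv(outdir / "territory_counts.tsv", sep="\t")
        rate = neurogenesis_rate(assignment)
        rate.to_csv(outdir / "neurogenesis_rate.tsv", sep="\t")
        record("dynamics", n_stages=comp.counts.shape[0])

    # --- double-positive analysis --------------------------------------
    if "dp" not in config.skip:
        neural_cells = assignment.index[(assignment["tissue"] == "neural").to_numpy()]
        if len(neural_cells):
            bm = binarize_expression(
                nm.subset_cells(neural_cells), km.marker_genes, method=config.binarize_method
            )
            groups = gate_cells(bm)
            stages = assignment.loc[neural_cells, "stage"]
            ratio = dp_ratio(groups, stages)
            ratio.to_csv(outdir / "dp_ratio.tsv", sep="\t")
            sim = dp_similarity(
                nm, groups, assignment.loc[neural_cells],
                default_gene_space(km, nm), min_cells=config.min_cells,
            )
            sim.to_csv(outdir / "dp_similarity.tsv", sep="\t")
            record("dp", n_dp=len(groups.dp), n_gated=len(groups.gated))

    report["output_hashes"] = {
        p.name: _hash_file(p) for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logging.getLogger("sctube").removeHandler(log_handler)
    log_handler.close()
    return report
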