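"""End-to-end orchestration of the ceRNA-network workflow.

Stages: dual-condition candidate selection -> miRNA-layer intersections ->
expression filter -> network assembly -> cohort correlation / survival
screens -> ORA -> per-condition GSEA -> cross-condition validation matrix.
Every intermediate is written as TSV into the output directory, and a
machine-readable report of all stage counts is produced, so the whole
selection cascade is auditable from the outputs alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .candidates import DETable, select_candidates, summarize_degs
from .cohort import CohortDataset, correlation_screen, survival_screen
from .config import PipelineConfig
from .enrichment import (
    GeneSetCollection,
    RankedList,
    build_validation_matrix,
    count_validated,
    gsea_preranked,
    ora,
)
from .network import (
    InteractionDB,
    MiRNAExpressionMatrix,
    assemble_network,
    filter_expressed,
    intersect_driver_binders,
    mirnas_targeting,
)

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labelled contract violation inside the pipeline."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow described by ``config``; return the report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(out)}

    # --- candidate selection -------------------------------------------
    @_stage("candidate_selection")
    def _candidates():
        kd = DETable.read_tsv(config.de_kd, "KD")
        ovx = DETable.read_tsv(config.de_ovx, "OVX")
        kd_up, kd_down = summarize_degs(kd, config.fdr_alpha)
        ovx_up, ovx_down = summarize_degs(ovx, config.fdr_alpha)
        cand = select_candidates(kd, ovx, config.fdr_alpha)
        cand.write_tsv(out / "candidates.tsv")
        report.update(
            kd_up=kd_up, kd_down=kd_down, kd_total=kd_up + kd_down,
            ovx_up=ovx_up, ovx_down=ovx_down, ovx_total=ovx_up + ovx_down,
            n_candidates=len(cand),
        )
        logger.info("candidate selection: %d genes", len(cand))
        background = sorted(set(kd.data["gene_id"]) | set(ovx.data["gene_id"]))
        return cand, background

    candidates, background = _candidates()

    # --- miRNA layer and network ---------------------------------------
    @_stage("network_builder")
    def _network():
        db = InteractionDB.read_tsv(config.interactions, config.driver_binders)
        target_binders = mirnas_targeting(db, candidates)
        inter = intersect_driver_binders(target_binders, db)
        expr = MiRNAExpressionMatrix.read_tsv(
            config.mirna_expression, config.mirna_groups
        )
        expressed = filter_expressed(
            inter, expr, config.log2_threshold, config.min_samples
        )
        net = assemble_network(config.driver_id, expressed, candidates, db)
        net.write_edgelist(out / "network_edges.tsv")
        net.write_graphml(out / "network.graphml")
        report.update(
            n_target_binders=len(target_binders),
            n_intersection=len(inter),
            n_expressed=len(expressed),
            n_nodes=net.n_nodes,
            n_edges=net.n_edges,
            n_mt_edges=len(net.mt_edges),
            n_driver_edges=len(net.driver_edges),
        )
        logger.info(
            "miRNA cascade: %d targeting -> %d driver-binding -> %d expressed; "
            "network %d nodes / %d edges",
            len(target_binders), len(inter), len(expressed),
            net.n_nodes, net.n_edges,
        )
        return net

    network = _network()

    # --- cohort screens (optional) -------------------------------------
    if config.cohort_expression:
        @_stage("cohort_stats")
        def _cohort():
            cohort = CohortDataset.read_tsv(
                config.cohort_expression,
                config.cohort_survival or None,
                cohort_label="cohort",
            )
            corr = correlation_screen(
                cohort, config.driver_id, candidates.gene_ids, config.fdr_alpha
            )
            corr.table.to_csv(out / "correlation_screen.tsv", sep="\t")
            report["n_corr_significant_positive"] = len(corr.significant_positive)
            if cohort.survival is not None:
                surv = survival_screen(cohort, candidates.gene_ids)
                surv.table.to_csv(out / "survival_screen.tsv", sep="\t")
                a = config.fdr_alpha
                os_sig = surv.table["os_p"] < a
                pfs_sig = surv.table["pfs_p"] < a
                report["n_surv_both"] = int((os_sig & pfs_sig).sum())
                report["n_surv_any"] = int((os_sig | pfs_sig).sum())

        _cohort()

    # --- enrichment and validation (optional) --------------------------
    if config.gene_sets:
        @_stage("enrichment")
        def _enrich():
            collection = GeneSetCollection.read_gmt(config.gene_sets)
            ora_table = ora(candidates.gene_ids, collection, background)
            ora_table.to_csv(out / "ora.tsv", sep="\t")
            nominated = sorted(
                ora_table.index[ora_table["p_adj"] < config.padj_threshold]
            )
            report["n_ora_significant"] = len(nominated)
            if not config.ranked_lists:
                return
            results = {}
            for cond in sorted(config.ranked_lists):
                ranked = RankedList.read_tsv(config.ranked_lists[cond])
                res = gsea_preranked(
                    ranked, collection,
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    condition=cond,
                )
                res.table.to_csv(out / f"gsea_{cond}.tsv", sep="\t")
                results[cond] = res
            rows = nominated if nominated else collection.names()
            matrix = build_validation_matrix(
                results, rows,
                nes_threshold=config.nes_threshold,
                padj_threshold=config.padj_threshold,
                condition_direction={
                    c: d for c, d in config.condition_direction.items()
                    if c in results
                },
            )
            matrix.write_tsv(out / "validation_matrix.tsv")
            any_names, n_any = count_validated(matrix, 1)
            all_names, n_all = count_validated(matrix, len(results))
            report.update(
                n_validated_any=n_any,
                validated_any=any_names,
                n_validated_all_conditions=n_all,
                validated_all_conditions=all_names,
                n_sign_consistent=int(matrix.sign_consistent.sum()),
            )

        _enrich()

    (out / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report
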