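"""End-to-end orchestration: differential expression, modification calls,
SNP QC, the association cascade, expression linkage, and the stage-count
summaries (one in the layer x direction x stage-count layout, one listing the
expression-linked SNPs with their concordance signs)."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import diffexpr
from .association import run_cascade, stage_summary
from .cohort import PairedCohort
from .config import PipelineConfig
from .expression_link import link_expression
from .modification import call_matrix
from .snp_qc import filter_snps

logger = logging.getLogger("regsnp")

__all__ = ["PipelineResult", "run_full_pipeline", "write_summary", "write_all"]


@dataclass
class PipelineResult:
    de_results: pd.DataFrame
    cnv_status: pd.DataFrame
    meth_status: pd.DataFrame
    qc_table: pd.DataFrame
    retained_snps: list
    cascade_records: pd.DataFrame
    link_records: pd.DataFrame
    stage_counts: pd.DataFrame
    linked_table: pd.DataFrame
    de_summary: dict


def run_full_pipeline(cohort: PairedCohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a paired cohort; deterministic given the inputs."""
    cfg = config or PipelineConfig()

    de = diffexpr.de_table(cohort.expr_tumor, cohort.expr_normal, threshold=cfg.de_p)
    selected = diffexpr.select_de_genes(de, cfg.de_p)
    de_summary = diffexpr.summarize_de(selected)
    logger.info("diffexpr: %d of %d genes selected at p < %g", len(selected), len(de), cfg.de_p)

    cnv_status = call_matrix(cohort.cn_diff, "cnv", cfg.cn)
    meth_status = call_matrix(cohort.beta_diff, "methylation", cfg.beta)

    retained, qc = filter_snps(
        cohort.genotypes_normal, cfg.maf, cfg.hwe, genotypes_tumor=cohort.genotypes_tumor
    )
    logger.info("snp_qc: %d of %d SNPs retained (maf >= %g, hwe p > %g)",
                len(retained), len(qc), cfg.maf, cfg.hwe)

    records = run_cascade(
        cohort.genotypes_normal,
        cohort.snp_gene_map,
        cn_diff=cohort.cn_diff,
        beta_diff=cohort.beta_diff,
        cnv_status=cnv_status,
        meth_status=meth_status,
        retained_snps=retained,
        models=tuple(cfg.models),
        thresholds=(cfg.t1, cfg.t2, cfg.t3),
    )
    counts = stage_summary(records)
    for row in counts.itertuples(index=False):
        logger.info("cascade %s/%s: fisher=%d regression=%d kw=%d",
                    row.layer, row.direction, row.fisher, row.regression, row.kw)

    links = link_expression(
        records, cohort.expr_tumor, cohort.expr_normal, cohort.genotypes_normal,
        expr_threshold=cfg.expr_p,
    )
    linked = links[links["expr_p"] < cfg.expr_p].reset_index(drop=True) if len(links) else links
    logger.info("expression link: %d of %d survivors significant at p < %g",
                len(linked), len(links), cfg.expr_p)

    counts = counts.merge(
        linked.groupby(["layer", "direction"])["snp_id"].nunique().rename("expression_linked"),
        on=["layer", "direction"], how="left",
    ).merge(
        linked[linked["concordance"] == "+"]
        .groupby(["layer", "direction"])["snp_id"].nunique().rename("concordant"),
        on=["layer", "direction"], how="left",
    )
    counts[["expression_linked", "concordant"]] = (
        counts[["expression_linked", "concordant"]].fillna(0).astype(int)
    )

    return PipelineResult(
        de_results=de,
        cnv_status=cnv_status,
        meth_status=meth_status,
        qc_table=qc,
        retained_snps=retained,
        cascade_records=records,
        link_records=links,
        stage_counts=counts,
        linked_table=linked,
        de_summary=de_summary,
    )


def write_summary(result: PipelineResult, out_dir) -> tuple[str, str]:
    """Write the two summary tables.

    ``stage_counts.tsv``: rows = {amplification, deletion, hyper, hypo},
    columns = counts at each stage (fisher, regression, kw,
    expression_linked, concordant). ``linked_snps.tsv``: one row per
    expression-linked SNP with its gene, layer, direction and concordance.
    """
    os.makedirs(out_dir, exist_ok=True)
    p1 = os.path.join(out_dir, "stage_counts.tsv")
    p2 = os.path.join(out_dir, "linked_snps.tsv")
    result.stage_counts.to_csv(p1, sep="\t", index=False)
    cols = ["layer", "direction", "gene_id", "snp_id", "expr_p", "concordance"]
    linked = result.linked_table
    (linked[cols] if len(linked) else pd.DataFrame(columns=cols)).to_csv(p2, sep="\t", index=False, float_format="%.6g")
    return p1, p2


def write_all(result: PipelineResult, out_dir) -> None:
    """Write every intermediate table plus the two summaries as TSV."""
    os.makedirs(out_dir, exist_ok=True)
    result.de_results.to_csv(os.path.join(out_dir, "de_results.tsv"), sep="\t", index=False, float_format="%.6g")
    result.cnv_status.to_csv(os.path.join(out_dir, "cnv_status.tsv"), sep="\t")
    result.meth_status.to_csv(os.path.join(out_dir, "meth_status.tsv"), sep="\t")
    result.qc_table.to_csv(os.path.join(out_dir, "snp_qc.tsv"), sep="\t", index=False, float_format="%.6g")
    result.cascade_records.to_csv(os.path.join(out_dir, "cascade_records.tsv"), sep="\t", index=False, float_format="%.6g")
    result.link_records.to_csv(os.path.join(out_dir, "link_records.tsv"), sep="\t", index=False, float_format="%.6g")
    write_summary(result, out_dir)
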