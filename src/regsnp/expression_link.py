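"""Expression linkage: do cascade-surviving SNP groupings also separate the
tumor/normal expression change, and is the change concordant with the
modification direction?

The expected expression direction of a modification follows the dosage /
promoter-repression model: amplification and hypomethylation push expression
up; deletion and hypermethylation push it down. A survivor is concordant
('+') when the median expression log-ratio of carriers of the tested allele
has that expected sign, discordant ('-') otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import kruskal_wallis
from .config import QUALITATIVE

__all__ = [
    "expression_group_test",
    "classify_concordance",
    "link_expression",
    "EXPECTED_SIGN",
]

EXPECTED_SIGN = {"amplification": 1, "deletion": -1, "hyper": -1, "hypo": 1}


def expression_group_test(log_ratios, codes) -> tuple[float, float]:
    """Rank test of expression log-ratios across SNP code groups.

    Two groups: two-sided Wilcoxon rank-sum (exact for small tie-free
    samples); three or more: Kruskal-Wallis. Returns (statistic, p).
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(log_ratios, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    levels = np.unique(x)
    groups = [y[x == lv] for lv in levels]
    groups = [g for g in groups if g.size]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty code groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    return kruskal_wallis(groups)


def classify_concordance(direction: str, median_log_ratio: float) -> str:
    """'+' when the carriers' median expression change matches the direction's
    expected sign, '-' when it opposes it, 'undetermined' at exactly zero."""
    expected = EXPECTED_SIGN[direction]
    if median_log_ratio == 0 or not np.isfinite(median_log_ratio):
        return "undetermined"
    return "+" if np.sign(median_log_ratio) == expected else "-"


def link_expression(
    cascade_records: pd.DataFrame,
    expr_tumor: pd.DataFrame,
    expr_normal: pd.DataFrame,
    genotypes_normal: pd.DataFrame,
    expr_threshold: float = 0.05,
    tested_allele: str = "minor",
) -> pd.DataFrame:
    """Test every full-cascade survivor for grouped expression change.

    When a SNP-gene-direction survived under both coding models, the
    qualitative grouping (simpler, two groups) is the one reported.
    Concordance is classified only for significant tests with a nonzero
    carrier median; otherwise it is 'undetermined'.
    """
    from .association import code_genotypes

    survivors = cascade_records[cascade_records["stage_passed"] == "kw"]
    if len(survivors) == 0:
        return pd.DataFrame(
            columns=[
                "snp_id", "gene_id", "layer", "direction", "model",
                "expr_stat", "expr_p", "median_log_ratio_carriers", "concordance",
            ]
        )
    # prefer the qualitative model when both passed for the same combination
    order = survivors["model"].map({QUALITATIVE: 0}).fillna(1)
    survivors = (
        survivors.assign(_order=order)
        .sort_values(["snp_id", "gene_id", "layer", "direction", "_order"])
        .drop_duplicates(subset=["snp_id", "gene_id", "layer", "direction"], keep="first")
    )
    records = []
    log_ratio = expr_tumor - expr_normal
    for row in survivors.itertuples(index=False):
        lr = log_ratio.loc[row.gene_id].to_numpy(float)
        coding = code_genotypes(
            genotypes_normal.loc[row.snp_id].to_numpy(), row.model, tested_allele, row.snp_id
        )
        stat, p = expression_group_test(lr, coding.codes)
        carriers = coding.codes >= 1
        med = float(np.median(lr[carriers & ~np.isnan(lr)])) if carriers.any() else np.nan
        concordance = (
            classify_concordance(row.direction, med) if p < expr_threshold else "undetermined"
        )
        records.append(
            {
                "snp_id": row.snp_id,
                "gene_id": row.gene_id,
                "layer": row.layer,
                "direction": row.direction,
                "model": row.model,
                "expr_stat": stat,
                "expr_p": p,
                "median_log_ratio_carriers": med,
                "concordance": concordance,
            }
        )
    return pd.DataFrame(records)
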