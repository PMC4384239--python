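"""Expression normalization and paired differential-expression testing.

Quantile normalization forces every sample (column) onto the same empirical
distribution — the per-rank across-column means — and each gene is then
tested with a paired t-test on tumor minus normal log2 intensities. Genes
with undefined statistics (zero-variance differences) are reported with a
missing p-value and are never selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "paired_t_test",
    "bonferroni_threshold",
    "de_table",
    "select_de_genes",
    "summarize_de",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a feature x sample matrix.

    After normalization every column holds the identical sorted multiset (the
    per-rank across-column means). Ties within a column receive the mean of
    the reference values over their rank range.
    """
    if matrix.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix (no NaNs)")
    reference = np.sort(values, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def paired_t_test(tumor_row, normal_row) -> tuple[float, float, int]:
    """Paired t on tumor minus normal; pairs with any missing value dropped.

    Returns (t, two-sided p, df). Zero-variance differences yield
    (nan, nan, df): the statistic is undefined and the gene is never selected.
    """
    t_arr = np.asarray(tumor_row, dtype=float)
    n_arr = np.asarray(normal_row, dtype=float)
    keep = ~(np.isnan(t_arr) | np.isnan(n_arr))
    d = t_arr[keep] - n_arr[keep]
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs >= 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return float("nan"), float("nan"), df
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling the family-wise error rate."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1): {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1: {m}")
    return alpha / m


def de_table(
    expr_tumor: pd.DataFrame,
    expr_normal: pd.DataFrame,
    threshold: float = 1e-9,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-gene paired-t results: t, p, mean log-ratio, direction, selected."""
    if list(expr_tumor.columns) != list(expr_normal.columns):
        raise ValueError("tumor and normal matrices must share patient columns")
    if not expr_tumor.index.equals(expr_normal.index):
        raise ValueError("tumor and normal matrices must share gene rows")
    if normalize:
        expr_tumor = quantile_normalize(expr_tumor)
        expr_normal = quantile_normalize(expr_normal)
    records = []
    for gene_id in expr_tumor.index:
        t, p, _df = paired_t_test(expr_tumor.loc[gene_id], expr_normal.loc[gene_id])
        mean_lr = float(np.nanmean(expr_tumor.loc[gene_id] - expr_normal.loc[gene_id]))
        records.append(
            {
                "gene_id": gene_id,
                "t_stat": t,
                "p_value": p,
                "mean_log_ratio": mean_lr,
                "direction": "up" if mean_lr > 0 else "down",
                "selected": bool(p < threshold) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(records)


def select_de_genes(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Genes with a defined p below threshold, labeled up/down."""
    defined = results["p_value"].notna()
    return results.loc[defined & (results["p_value"] < threshold)].reset_index(drop=True)


def summarize_de(selected: pd.DataFrame) -> dict:
    """Counts and integer percentages of up/down genes among the selected set.

    With zero selected genes the percentages are undefined (None).
    """
    total = len(selected)
    n_down = int((selected["direction"] == "down").sum()) if total else 0
    n_up = total - n_down
    if total == 0:
        return {"total": 0, "down": 0, "up": 0, "pct_down": None, "pct_up": None}
    return {
        "total": total,
        "down": n_down,
        "up": n_up,
        "pct_down": round(100 * n_down / total),
        "pct_up": round(100 * n_up / total),
    }
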