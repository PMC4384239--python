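"""The regulatory-SNP association cascade.

For each QC-passing SNP paired with its host gene, each modification layer
(CNV, methylation), each direction (amplification/deletion, hyper/hypo) and
each genotype coding model (qualitative carrier indicator, quantitative
allele count), three tests are applied in sequence, each gated at its own
threshold (default 0.01):

1. Fisher's exact test on the code x (modified, not modified) contingency
   table (2x2 for the qualitative model, up to 3x2 Freeman-Halton for the
   quantitative model);
2. ordinary least squares of the modification magnitude (CN_dif or the beta
   difference) on the code, with a t-test on the slope;
3. the Kruskal-Wallis test on magnitudes grouped by code level (equivalent to
   the Wilcoxon rank-sum test for two groups).

A SNP counts once per direction in the stage summary if it passes under
either coding model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from math import comb, exp, inf, log

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING
from .config import MODELS, QUALITATIVE, QUANTITATIVE
from .modification import AMPLIFIED, DELETED, HYPER, HYPO

__all__ = [
    "SnpCoding",
    "code_genotypes",
    "build_contingency",
    "fisher_exact",
    "regression_stage",
    "kruskal_wallis",
    "run_cascade",
    "DIRECTIONS",
]

# layer -> directions, and the modified-status label of each direction
DIRECTIONS = {
    "cnv": {"amplification": AMPLIFIED, "deletion": DELETED},
    "methylation": {"hyper": HYPER, "hypo": HYPO},
}
STAGES = ("none", "fisher", "regression", "kw")

_TIE_RTOL = 1e-7  # relative tolerance when comparing table probabilities


@dataclass
class SnpCoding:
    """Per-patient numeric code of one SNP under one model.

    ``codes`` holds floats with NaN for missing genotypes; ``untestable`` is
    set when the non-missing codes are constant (no contrast to test).
    """

    snp_id: str
    model: str
    codes: np.ndarray
    tested_allele: str = "minor"
    untestable: bool = False


def code_genotypes(genotype_row, model: str, tested_allele: str = "minor", snp_id: str = "") -> SnpCoding:
    """Code a genotype row: carrier indicator {0,1} or allele count {0,1,2}.

    ``tested_allele`` selects which allele carrier status refers to; with
    'major' the counts are reflected (2 - count).
    """
    if model not in MODELS:
        raise ValueError(f"unknown coding model: {model!r}")
    g = np.asarray(genotype_row, dtype=float)
    g[g == MISSING] = np.nan
    if tested_allele == "major":
        g = 2 - g
    elif tested_allele != "minor":
        raise ValueError(f"tested_allele must be 'minor' or 'major': {tested_allele!r}")
    codes = (g >= 1).astype(float) if model == QUALITATIVE else g
    codes[np.isnan(g)] = np.nan
    defined = codes[~np.isnan(codes)]
    untestable = defined.size == 0 or bool(np.all(defined == defined[0]))
    return SnpCoding(snp_id=snp_id, model=model, codes=codes, tested_allele=tested_allele, untestable=untestable)


def build_contingency(codes: np.ndarray, modified: np.ndarray) -> np.ndarray:
    """Code-level x (modified, not modified) patient counts.

    Rows are the code levels actually present (ascending), so the table is
    2x2 under the qualitative model and up to 3x2 under the quantitative one.
    Patients with a missing code or status are excluded.
    """
    codes = np.asarray(codes, dtype=float)
    modified = np.asarray(modified, dtype=float)
    keep = ~(np.isnan(codes) | np.isnan(modified))
    codes, modified = codes[keep], modified[keep].astype(bool)
    if codes.size == 0:
        raise ValueError("no patient has both a genotype code and a status")
    levels = np.unique(codes)
    table = np.zeros((levels.size, 2), dtype=int)
    for i, lv in enumerate(levels):
        at = codes == lv
        table[i, 0] = int((at & modified).sum())
        table[i, 1] = int((at & ~modified).sum())
    return table


@lru_cache(maxsize=200_000)
def _fisher_cached(row_sums: tuple[int, ...], a_obs: tuple[int, ...]) -> float:
    """Two-sided exact p for an r x 2 table with the given row sums and
    first-column (modified) counts, by enumeration over margin-preserving
    tables under the multivariate hypergeometric null."""
    c1 = sum(a_obs)
    n = sum(row_sums)
    if c1 == 0 or c1 == n or any(r == 0 for r in row_sums):
        # a zero margin admits a single attainable table
        return 1.0

    log_rows = [[_logcomb(r, a) for a in range(r + 1)] for r in row_sums]
    denom = _logcomb(n, c1)

    def table_logps():
        ranges = [range(min(r, c1) + 1) for r in row_sums[:-1]]
        for head in product(*ranges):
            rest = c1 - sum(head)
            if 0 <= rest <= row_sums[-1]:
                yield head + (rest,), sum(
                    log_rows[i][a] for i, a in enumerate(head + (rest,))
                ) - denom

    logp_obs = sum(log_rows[i][a] for i, a in enumerate(a_obs)) - denom
    cutoff = logp_obs + log(1 + _TIE_RTOL)
    total = 0.0
    for _cells, logp in table_logps():
        if logp <= cutoff:
            total += exp(logp)
    return min(1.0, total)


@lru_cache(maxsize=4096)
def _logcomb(n: int, k: int) -> float:
    return log(comb(n, k)) if 0 <= k <= n else -inf


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided exact test for a 2x2 or 3x2 contingency table.

    The p-value sums the probabilities of every margin-preserving table whose
    (multivariate) hypergeometric probability does not exceed the observed
    table's, with a relative tie tolerance of 1e-7.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[1] != 2 or not (2 <= t.shape[0] <= 3):
        raise ValueError(f"expected a 2x2 or 3x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency cells must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("contingency cells must be non-negative")
    return _fisher_cached(tuple(int(r) for r in t.sum(axis=1)), tuple(int(a) for a in t[:, 0]))


def regression_stage(codes, magnitudes) -> tuple[float, float]:
    """OLS of modification magnitude on the SNP code; t-test on the slope.

    Returns (slope, two-sided p). Constant magnitudes give (0, 1): a flat
    response carries no association. A perfect fit (zero residual variance
    with a nonzero slope) is reported as p = 0 with a warning.
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(magnitudes, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"regression needs >= 3 complete patients, got {n}")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("SNP code is constant; slope undefined")
    syy = ((y - y.mean()) ** 2).sum()
    if syy == 0:
        return 0.0, 1.0
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    sse = (resid**2).sum()
    if sse <= 1e-14 * syy:
        warnings.warn("zero residual variance; slope p-value reported as 0", stacklevel=2)
        return float(slope), 0.0
    se = np.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    return float(slope), float(2 * stats.t.sf(abs(t), n - 2))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df.

    For two groups this is equivalent to the two-sided Wilcoxon rank-sum test
    under the normal approximation. All values identical: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _status_to_modified(status_row: np.ndarray, label: str) -> np.ndarray:
    """Indicator of 'modified in this direction'; other statuses pool as not."""
    out = np.full(status_row.shape, np.nan)
    defined = pd.notna(status_row)
    out[defined] = (status_row[defined] == label).astype(float)
    return out


def run_cascade(
    genotypes_normal: pd.DataFrame,
    snp_gene_map: pd.Series,
    cn_diff: pd.DataFrame | None = None,
    beta_diff: pd.DataFrame | None = None,
    cnv_status: pd.DataFrame | None = None,
    meth_status: pd.DataFrame | None = None,
    retained_snps=None,
    models=MODELS,
    thresholds: tuple[float, float, float] = (0.01, 0.01, 0.01),
    tested_allele: str = "minor",
) -> pd.DataFrame:
    """Run the three-stage cascade over every SNP-gene-layer-direction-model.

    Magnitude matrices and their status calls must be supplied together for a
    layer to be tested. Pairs whose status vector lacks contrast (no modified
    or no unmodified patient) are skipped. Returns one record per tested
    combination with the stage p-values and ``stage_passed``.
    """
    from .modification import call_matrix

    t1, t2, t3 = thresholds
    layers = {}
    if cn_diff is not None:
        layers["cnv"] = (cn_diff, cnv_status if cnv_status is not None else call_matrix(cn_diff, "cnv"))
    if beta_diff is not None:
        layers["methylation"] = (
            beta_diff,
            meth_status if meth_status is not None else call_matrix(beta_diff, "methylation"),
        )
    if not layers:
        raise ValueError("at least one modification layer (cn_diff or beta_diff) is required")

    snps = list(genotypes_normal.index) if retained_snps is None else list(retained_snps)
    records = []
    for snp_id in snps:
        gene_id = snp_gene_map.get(snp_id)
        if gene_id is None or pd.isna(gene_id):
            continue
        geno_row = genotypes_normal.loc[snp_id].to_numpy()
        codings = {m: code_genotypes(geno_row, m, tested_allele, snp_id) for m in models}
        for layer, (magnitude, status) in layers.items():
            if gene_id not in magnitude.index:
                continue
            mags = magnitude.loc[gene_id].to_numpy(float)
            status_row = status.loc[gene_id].to_numpy()
            for direction, label in DIRECTIONS[layer].items():
                modified = _status_to_modified(status_row, label)
                n_mod = np.nansum(modified)
                n_unmod = np.nansum(1 - modified)
                if n_mod == 0 or n_unmod == 0:
                    continue  # Fisher degenerate; pair skipped
                for model in models:
                    coding = codings[model]
                    if coding.untestable:
                        continue
                    rec = {
                        "snp_id": snp_id,
                        "gene_id": gene_id,
                        "layer": layer,
                        "direction": direction,
                        "model": model,
                        "fisher_p": np.nan,
                        "regression_slope": np.nan,
                        "regression_p": np.nan,
                        "kw_stat": np.nan,
                        "kw_p": np.nan,
                        "stage_passed": "none",
                    }
                    table = build_contingency(coding.codes, modified)
                    rec["n_per_cell"] = ";".join(",".join(map(str, r)) for r in table)
                    rec["fisher_p"] = fisher_exact(table)
                    if rec["fisher_p"] < t1:
                        rec["stage_passed"] = "fisher"
                        keep = ~(np.isnan(coding.codes) | np.isnan(mags))
                        try:
                            slope, reg_p = regression_stage(coding.codes[keep], mags[keep])
                        except ValueError:
                            slope, reg_p = np.nan, np.nan
                        rec["regression_slope"], rec["regression_p"] = slope, reg_p
                        if np.isfinite(reg_p) and reg_p < t2:
                            rec["stage_passed"] = "regression"
                            levels = np.unique(coding.codes[keep])
                            groups = [mags[keep][coding.codes[keep] == lv] for lv in levels]
                            h, kw_p = kruskal_wallis(groups)
                            rec["kw_stat"], rec["kw_p"] = h, kw_p
                            if kw_p < t3:
                                rec["stage_passed"] = "kw"
                    records.append(rec)
    columns = [
        "snp_id", "gene_id", "layer", "direction", "model",
        "fisher_p", "regression_slope", "regression_p", "kw_stat", "kw_p",
        "stage_passed", "n_per_cell",
    ]
    return pd.DataFrame(records, columns=columns)


def stage_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per layer x direction distinct-SNP counts surviving each stage.

    A SNP counts once per direction if it passes a stage under either coding
    model, so counts are monotone non-increasing along the cascade.
    """
    rows = []
    rank = {s: i for i, s in enumerate(STAGES)}
    for layer, dirs in DIRECTIONS.items():
        for direction in dirs:
            sub = records[(records.get("layer") == layer) & (records.get("direction") == direction)] if len(records) else records
            counts = {}
            for stage in ("fisher", "regression", "kw"):
                if len(sub):
                    passed = sub["stage_passed"].map(rank) >= rank[stage]
                    counts[stage] = int(sub.loc[passed, "snp_id"].nunique())
                else:
                    counts[stage] = 0
            rows.append({"layer": layer, "direction": direction, **counts})
    return pd.DataFrame(rows, columns=["layer", "direction", "fisher", "regression", "kw"])
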