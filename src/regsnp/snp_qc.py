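"""SNP quality control: minor-allele frequency, exact Hardy-Weinberg test,
and Bowker's symmetry test on paired tumor/normal genotype calls.

QC is computed on normal-tissue (germline) genotypes; the Bowker test asks
whether tumor calls deviate asymmetrically from their germline counterparts,
which would flag systematic somatic genotype shifts.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import MISSING

__all__ = [
    "minor_allele_frequency",
    "hwe_exact_test",
    "bowker_test",
    "paired_genotype_table",
    "filter_snps",
]


def minor_allele_frequency(genotype_row) -> float:
    """MAF over 2n alleles from non-missing minor-allele-count calls.

    The returned frequency is min(freq of the two alleles), so a row where the
    nominally minor allele in fact dominates still reports a value <= 0.5.
    """
    g = np.asarray(genotype_row)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("all genotype calls missing")
    freq = g.sum() / (2 * g.size)
    return float(min(freq, 1 - freq))


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed minor-allele count; enumerates every compatible
    heterozygote count and sums the probabilities of configurations no more
    likely than the observed one. Monomorphic rows have a single attainable
    configuration, so p = 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("at least one genotype call required")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    if n_minor == 0:
        return 1.0

    # log P(het = h | allele count) ∝ log(2^h) - log(h!) - log(n_aa!) - log(n_AA!)
    def log_weight(h: int) -> float:
        n_aa = (n_minor - h) // 2
        n_AA = n - h - n_aa
        return h * np.log(2) - gammaln(h + 1) - gammaln(n_aa + 1) - gammaln(n_AA + 1)

    # possible het counts share the parity of the minor-allele count
    hs = list(range(n_minor % 2, n_minor + 1, 2))
    logw = np.array([log_weight(h) for h in hs])
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    obs_index = hs.index(n_het)
    p_obs = probs[obs_index]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def bowker_test(table: np.ndarray, fixed_df: bool = False) -> tuple[float, int, float]:
    """Bowker's chi-square test of symmetry for a 3x3 paired genotype table.

    Rows index the normal-tissue call, columns the tumor call. Only
    off-diagonal pairs with n_ij + n_ji > 0 are informative; by default df
    counts those pairs (``fixed_df=True`` forces the textbook df = 3).
    With no informative pair: chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"expected a 3x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    chi2 = 0.0
    informative = 0
    for i in range(3):
        for j in range(i + 1, 3):
            tot = t[i, j] + t[j, i]
            if tot > 0:
                chi2 += (t[i, j] - t[j, i]) ** 2 / tot
                informative += 1
    df = 3 if fixed_df else informative
    if df == 0:
        return 0.0, 0, 1.0
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def paired_genotype_table(normal_row, tumor_row) -> np.ndarray:
    """3x3 normal-vs-tumor genotype cross-tabulation over complete pairs."""
    n = np.asarray(normal_row)
    t = np.asarray(tumor_row)
    keep = (n != MISSING) & (t != MISSING)
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (n[keep], t[keep]), 1)
    return table


def filter_snps(
    genotypes_normal: pd.DataFrame,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.05,
    genotypes_tumor: pd.DataFrame | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Retain SNPs with MAF >= maf_min and HWE p > hwe_p_min.

    Emits the full QC table for every SNP; when tumor genotypes are supplied
    the Bowker symmetry statistics are included.
    """
    records = []
    for snp_id, row in genotypes_normal.iterrows():
        g = row.to_numpy()
        g = g[g != MISSING]
        if g.size == 0:
            rec = {"snp_id": snp_id, "maf": np.nan, "hwe_p": np.nan, "passes": False}
        else:
            maf = minor_allele_frequency(g)
            counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            hwe_p = hwe_exact_test(*counts)
            rec = {
                "snp_id": snp_id,
                "maf": maf,
                "hwe_p": hwe_p,
                "passes": bool(maf >= maf_min and hwe_p > hwe_p_min),
            }
        if genotypes_tumor is not None:
            table = paired_genotype_table(row, genotypes_tumor.loc[snp_id])
            chi2, df, p = bowker_test(table)
            rec.update({"bowker_chi2": chi2, "bowker_df": df, "bowker_p": p})
        records.append(rec)
    qc = pd.DataFrame(records)
    retained = qc.loc[qc["passes"], "snp_id"].tolist()
    return retained, qc
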