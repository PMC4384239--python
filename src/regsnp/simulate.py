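"""Synthetic paired tumor/normal cohorts with planted regulatory SNPs.

The generative model, stage by stage:

1. Germline genotypes per SNP are drawn from Hardy-Weinberg proportions
   (p^2, 2pq, q^2) at a minor-allele frequency sampled uniformly from
   ``maf_range``. Tumor genotypes equal the germline calls except for
   independent somatic flips at ``somatic_flip_rate`` (a flip moves the call
   uniformly to one of the two other genotypes).
2. Per-gene copy-number differences (CN_dif, tumor minus normal) and
   methylation beta-differences are Gaussian noise plus any planted
   SNP-driven shifts: delta times the code of the driving SNP under its
   coding model (carrier indicator or allele count). Beta-differences are
   clipped to [-1, 1].
3. Expression log-ratios couple positively to CN_dif and negatively to the
   beta-difference (promoter methylation represses), plus planted
   differential-expression shifts and noise; expr_tumor = expr_normal +
   log-ratio.

Fixing ``config.seed`` fixes every layer bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MISSING, PairedCohort
from .config import (
    QUALITATIVE,
    ParameterError,
    SimulationConfig,
    gene_names,
    patient_names,
    snp_names,
)

__all__ = [
    "simulate_genotypes",
    "simulate_modifications",
    "simulate_expression",
    "simulate_cohort",
]


def _code_row(genotypes: np.ndarray, model: str) -> np.ndarray:
    """Numeric SNP code per patient; missing calls contribute 0 effect."""
    g = np.where(genotypes == MISSING, 0, genotypes).astype(float)
    if model == QUALITATIVE:
        return (g >= 1).astype(float)
    return g


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mafs=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw germline (normal) and somatically perturbed (tumor) genotypes.

    Returns (genotypes_normal, genotypes_tumor, maf_per_snp) with genotypes
    coded as minor-allele counts and ``maf_per_snp`` holding the population
    frequencies the rows were drawn from (not the realized sample MAFs).
    ``mafs`` overrides the per-SNP frequencies (one per SNP, in [0, 0.5]),
    bypassing sampling from ``maf_range`` — useful for degenerate edge cases.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_snps, n = config.n_snps, config.n_patients
    snps, patients = snp_names(n_snps), patient_names(n)

    if mafs is None:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=n_snps)
    else:
        maf = np.asarray(mafs, dtype=float)
        if maf.shape != (n_snps,) or maf.min() < 0 or maf.max() > 0.5:
            raise ParameterError("mafs must give one frequency in [0, 0.5] per SNP")
    p_hom_major = (1 - maf) ** 2
    p_het = 2 * maf * (1 - maf)
    u = rng.random((n_snps, n))
    normal = (u >= p_hom_major[:, None]).astype(np.int8) + (
        u >= (p_hom_major + p_het)[:, None]
    ).astype(np.int8)

    tumor = normal.copy()
    if config.somatic_flip_rate > 0:
        flips = rng.random((n_snps, n)) < config.somatic_flip_rate
        # uniform move to one of the two other genotypes
        step = rng.integers(1, 3, size=(n_snps, n), dtype=np.int8)
        tumor = np.where(flips, (tumor + step) % 3, tumor).astype(np.int8)

    if config.missing_rate > 0:
        for mat in (normal, tumor):
            miss = rng.random((n_snps, n)) < config.missing_rate
            mat[miss] = MISSING

    gn = pd.DataFrame(normal, index=snps, columns=patients)
    gt = pd.DataFrame(tumor, index=snps, columns=patients)
    return gn, gt, pd.Series(maf, index=snps, name="maf")


def _planted_matrix(
    config: SimulationConfig,
    genotypes_normal: pd.DataFrame,
    effects,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    n_genes, n = config.n_genes, config.n_patients
    mat = rng.normal(0.0, noise_sd, size=(n_genes, n)) if noise_sd > 0 else np.zeros((n_genes, n))
    gene_index = {g: i for i, g in enumerate(gene_names(n_genes))}
    monomorphic: list[str] = []
    for eff in effects:
        row = genotypes_normal.loc[eff.snp_id].to_numpy()
        codes = _code_row(row, eff.model)
        non_missing = row[row != MISSING]
        if non_missing.size and np.all(non_missing == non_missing[0]):
            monomorphic.append(eff.snp_id)
        mat[gene_index[eff.gene_id]] += eff.delta * codes
    return mat, monomorphic


def simulate_modifications(
    config: SimulationConfig,
    genotypes_normal: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Generate CN_dif and beta-difference matrices from planted effects.

    Genes without a planted effect are pure noise. Beta differences are
    clipped to [-1, 1]. Returns the two matrices plus the ids of planted SNPs
    that came out monomorphic in the realized cohort (flagged, not fatal).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes, patients = gene_names(config.n_genes), patient_names(config.n_patients)
    cn, mono_cn = _planted_matrix(
        config, genotypes_normal, config.planted_cnv_effects, config.cn_noise_sd, rng
    )
    beta, mono_me = _planted_matrix(
        config, genotypes_normal, config.planted_meth_effects, config.beta_noise_sd, rng
    )
    beta = np.clip(beta, -1.0, 1.0)
    cn_diff = pd.DataFrame(cn, index=genes, columns=patients)
    beta_diff = pd.DataFrame(beta, index=genes, columns=patients)
    return cn_diff, beta_diff, sorted(set(mono_cn + mono_me))


def simulate_expression(
    config: SimulationConfig,
    cn_diff: pd.DataFrame,
    beta_diff: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Couple expression log-ratios to the modification layers.

    log-ratio = expr_cn_coupling * CN_dif - expr_meth_coupling * beta_diff
    + planted DE shift + Gaussian noise; expr_normal is baseline noise and
    expr_tumor = expr_normal + log-ratio (log2 intensity scale).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    genes, patients = list(cn_diff.index), list(cn_diff.columns)
    shape = cn_diff.shape
    log_ratio = (
        config.expr_cn_coupling * cn_diff.to_numpy()
        - config.expr_meth_coupling * beta_diff.to_numpy()
    )
    if config.planted_de_effects:
        gene_index = {g: i for i, g in enumerate(genes)}
        for gene_id, shift in config.planted_de_effects:
            log_ratio[gene_index[gene_id]] += shift
    if config.expr_noise_sd > 0:
        log_ratio = log_ratio + rng.normal(0.0, config.expr_noise_sd, size=shape)
        normal = config.expr_baseline + rng.normal(0.0, config.expr_noise_sd, size=shape)
    else:
        normal = np.full(shape, config.expr_baseline)
    expr_normal = pd.DataFrame(normal, index=genes, columns=patients)
    expr_tumor = pd.DataFrame(normal + log_ratio, index=genes, columns=patients)
    return expr_tumor, expr_normal


def _default_snp_gene_map(config: SimulationConfig) -> pd.Series:
    """Round-robin host-gene assignment, overridden for planted SNPs."""
    snps, genes = snp_names(config.n_snps), gene_names(config.n_genes)
    mapping = {s: genes[i % config.n_genes] for i, s in enumerate(snps)}
    for eff in config.planted_cnv_effects + config.planted_meth_effects:
        mapping[eff.snp_id] = eff.gene_id
    return pd.Series(mapping, name="gene_id").reindex(snps)


def simulate_cohort(config: SimulationConfig) -> PairedCohort:
    """Generate a full paired cohort; ``truth`` records every planted effect."""
    rng = np.random.default_rng(config.seed)
    gn, gt, maf = simulate_genotypes(config, rng)
    cn_diff, beta_diff, monomorphic = simulate_modifications(config, gn, rng)
    expr_tumor, expr_normal = simulate_expression(config, cn_diff, beta_diff, rng)

    rows = []
    for kind, effects in (
        ("cnv", config.planted_cnv_effects),
        ("methylation", config.planted_meth_effects),
    ):
        for eff in effects:
            rows.append(
                {
                    "kind": kind,
                    "snp_id": eff.snp_id,
                    "gene_id": eff.gene_id,
                    "delta": eff.delta,
                    "model": eff.model,
                    "monomorphic": eff.snp_id in monomorphic,
                }
            )
    for gene_id, shift in config.planted_de_effects:
        rows.append(
            {
                "kind": "de",
                "snp_id": "",
                "gene_id": gene_id,
                "delta": shift,
                "model": "",
                "monomorphic": False,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["kind", "snp_id", "gene_id", "delta", "model", "monomorphic"]
    )
    return PairedCohort(
        genotypes_normal=gn,
        genotypes_tumor=gt,
        cn_diff=cn_diff,
        beta_diff=beta_diff,
        expr_tumor=expr_tumor,
        expr_normal=expr_normal,
        snp_gene_map=_default_snp_gene_map(config),
        truth=truth,
    )
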