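"""Generator behavior: HWE sampling, somatic flips, planted effects, coupling."""

import numpy as np
import pandas as pd
import pytest

from regsnp import ParameterError, PlantedEffect, SimulationConfig, simulate_cohort
from regsnp.cohort import MISSING
from regsnp.simulate import (
    simulate_expression,
    simulate_genotypes,
    simulate_modifications,
)
from regsnp.snp_qc import bowker_test, paired_genotype_table


def test_invalid_maf_range_rejected():
    with pytest.raises(ParameterError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ParameterError):
        SimulationConfig(maf_range=(0.1, 0.6))


def test_planted_effect_must_reference_existing_ids():
    with pytest.raises(ParameterError):
        SimulationConfig(
            n_genes=5, n_snps=5,
            planted_cnv_effects=[PlantedEffect("snp99999", "gene0001", 0.5)],
        )


def test_maf_zero_gives_monomorphic_hom_major_rows():
    cfg = SimulationConfig(n_patients=20, n_genes=2, n_snps=3, seed=1)
    gn, gt, _ = simulate_genotypes(cfg, mafs=[0.0, 0.0, 0.0])
    assert (gn.to_numpy() == 0).all()
    assert (gt.to_numpy() == 0).all()


def test_genotype_frequencies_match_hwe_proportions():
    """At MAF 0.5 and n = 10,000 the three genotype frequencies should land
    within 3 binomial SEs of (0.25, 0.5, 0.25)."""
    n = 10_000
    cfg = SimulationConfig(n_patients=n, n_genes=1, n_snps=1, somatic_flip_rate=0, seed=5)
    gn, _, _ = simulate_genotypes(cfg, mafs=[0.5])
    row = gn.to_numpy()[0]
    for geno, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
        freq = (row == geno).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) <= 3 * se


def test_zero_flip_rate_means_tumor_equals_normal():
    cfg = SimulationConfig(n_patients=32, n_genes=5, n_snps=50, somatic_flip_rate=0, seed=3)
    gn, gt, _ = simulate_genotypes(cfg)
    pd.testing.assert_frame_equal(gn, gt)


def test_zero_flip_rate_gives_zero_bowker_chi2_for_every_snp():
    cfg = SimulationConfig(n_patients=32, n_genes=5, n_snps=40, somatic_flip_rate=0, seed=9)
    cohort = simulate_cohort(cfg)
    for snp_id in cohort.genotypes_normal.index:
        table = paired_genotype_table(
            cohort.genotypes_normal.loc[snp_id], cohort.genotypes_tumor.loc[snp_id]
        )
        chi2, _df, p = bowker_test(table)
        assert chi2 == 0.0 and p == 1.0


def test_flips_move_to_a_different_genotype():
    cfg = SimulationConfig(n_patients=200, n_genes=2, n_snps=50, somatic_flip_rate=0.5, seed=2)
    gn, gt, _ = simulate_genotypes(cfg)
    flipped = gn.to_numpy() != gt.to_numpy()
    assert flipped.mean() == pytest.approx(0.5, abs=0.05)


def test_null_generator_gives_all_zero_cn():
    cfg = SimulationConfig(n_patients=10, n_genes=8, n_snps=5, cn_noise_sd=0, beta_noise_sd=0, seed=1)
    gn, _, _ = simulate_genotypes(cfg)
    cn, beta, mono = simulate_modifications(cfg, gn)
    assert (cn.to_numpy() == 0).all()
    assert (beta.to_numpy() == 0).all()
    assert mono == []


def test_planted_qualitative_effect_shifts_carrier_mean():
    """delta = 0.6 qualitative: carrier-mean CN within 3 SEs of 0.6,
    non-carrier mean within 3 SEs of 0."""
    n = 1000
    cfg = SimulationConfig(
        n_patients=n, n_genes=3, n_snps=3, cn_noise_sd=0.1,
        planted_cnv_effects=[PlantedEffect("snp00001", "gene0001", 0.6, "qualitative")],
        seed=4,
    )
    gn, _, _ = simulate_genotypes(cfg)
    cn, _, _ = simulate_modifications(cfg, gn)
    carriers = gn.loc["snp00001"].to_numpy() >= 1
    vals = cn.loc["gene0001"].to_numpy()
    se = 0.1 / np.sqrt(max(carriers.sum(), 1))
    assert abs(vals[carriers].mean() - 0.6) <= 3 * se
    se0 = 0.1 / np.sqrt((~carriers).sum())
    assert abs(vals[~carriers].mean()) <= 3 * se0


def test_beta_differences_clipped_to_unit_interval():
    cfg = SimulationConfig(
        n_patients=50, n_genes=2, n_snps=2,
        planted_meth_effects=[PlantedEffect("snp00001", "gene0001", 2.0, "quantitative")],
        seed=6,
    )
    cohort = simulate_cohort(cfg)
    beta = cohort.beta_diff.to_numpy()
    assert beta.min() >= -1 and beta.max() <= 1


def test_monomorphic_planted_snp_flagged_in_truth():
    cfg = SimulationConfig(
        n_patients=4, n_genes=2, n_snps=2,
        planted_cnv_effects=[PlantedEffect("snp00001", "gene0001", 0.5)],
        seed=0,
    )
    gn, _, _ = simulate_genotypes(cfg, mafs=[0.0, 0.3])
    _cn, _beta, mono = simulate_modifications(cfg, gn)
    assert mono == ["snp00001"]


def test_zero_couplings_and_noise_make_expression_identical():
    cfg = SimulationConfig(
        n_patients=10, n_genes=5, n_snps=5,
        expr_cn_coupling=0, expr_meth_coupling=0, expr_noise_sd=0, seed=8,
    )
    cohort = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(cohort.expr_tumor, cohort.expr_normal)


def test_cn_coupling_drives_positive_expression_correlation():
    """Coupling 1.0 with small noise: per-gene corr(CN_dif, log-ratio) > 0.5."""
    cfg = SimulationConfig(
        n_patients=1000, n_genes=4, n_snps=4, cn_noise_sd=0.5,
        expr_cn_coupling=1.0, expr_meth_coupling=0.0, expr_noise_sd=0.2, seed=10,
    )
    cohort = simulate_cohort(cfg)
    lr = (cohort.expr_tumor - cohort.expr_normal).to_numpy()
    cn = cohort.cn_diff.to_numpy()
    for g in range(4):
        assert np.corrcoef(cn[g], lr[g])[0, 1] > 0.5


def test_planted_de_shift_downregulates_gene():
    cfg = SimulationConfig(
        n_patients=32, n_genes=5, n_snps=5,
        planted_de_effects=[("gene0003", -1.0)], expr_noise_sd=0.3, seed=12,
    )
    cohort = simulate_cohort(cfg)
    lr = (cohort.expr_tumor - cohort.expr_normal).loc["gene0003"]
    assert lr.mean() < 0


def test_seed_fixes_cohort_bit_for_bit(tmp_path):
    cfg = SimulationConfig(n_patients=8, n_genes=10, n_snps=20, missing_rate=0.05, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    for attr in ("genotypes_normal", "genotypes_tumor", "cn_diff", "beta_diff",
                 "expr_tumor", "expr_normal"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))


def test_missing_rate_produces_missing_calls():
    cfg = SimulationConfig(n_patients=100, n_genes=2, n_snps=50, missing_rate=0.1, seed=14)
    gn, gt, _ = simulate_genotypes(cfg)
    assert (gn.to_numpy() == MISSING).mean() == pytest.approx(0.1, abs=0.02)


def test_roundtrip_through_tsv_directory(tmp_path, planted_cohort):
    _cfg, cohort = planted_cohort
    cohort.to_dir(tmp_path / "cohort")
    back = type(cohort).from_dir(tmp_path / "cohort")
    pd.testing.assert_frame_equal(cohort.genotypes_normal, back.genotypes_normal.astype(np.int8))
    assert np.allclose(cohort.cn_diff.to_numpy(), back.cn_diff.to_numpy(), atol=1e-5)
    assert list(back.snp_gene_map.index) == list(cohort.snp_gene_map.index)
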