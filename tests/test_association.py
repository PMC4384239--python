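"""Genotype coding, contingency building, the three cascade tests, run_cascade."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regsnp import PlantedEffect, SimulationConfig, simulate_cohort
from regsnp.association import (
    build_contingency,
    code_genotypes,
    fisher_exact,
    kruskal_wallis,
    regression_stage,
    run_cascade,
    stage_summary,
)
from regsnp.snp_qc import filter_snps


def fisher_oracle(table) -> float:
    """Brute-force two-sided exact p: enumerate every margin-preserving table
    via itertools, probabilities from scipy's multivariate hypergeometric."""
    t = np.asarray(table, int)
    row_sums = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    if c1 == 0 or c1 == t.sum() or (row_sums == 0).any():
        return 1.0
    dist = stats.multivariate_hypergeom(m=list(row_sums), n=c1)
    p_obs = dist.pmf(t[:, 0])
    total = 0.0
    for cells in product(*[range(r + 1) for r in row_sums]):
        if sum(cells) == c1:
            p = dist.pmf(list(cells))
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(1.0, total)


class TestCoding:
    def test_qualitative_het_carrier(self):
        coding = code_genotypes([1, 0, 2], "qualitative")
        np.testing.assert_array_equal(coding.codes, [1.0, 0.0, 1.0])

    def test_quantitative_counts_minor_alleles(self):
        coding = code_genotypes([2, 1, 0], "quantitative")
        np.testing.assert_array_equal(coding.codes, [2.0, 1.0, 0.0])

    def test_major_allele_reflection(self):
        coding = code_genotypes([2, 1, 0], "quantitative", tested_allele="major")
        np.testing.assert_array_equal(coding.codes, [0.0, 1.0, 2.0])

    def test_monomorphic_untestable(self):
        assert code_genotypes([0, 0, 0], "qualitative").untestable
        assert not code_genotypes([0, 1, 0], "qualitative").untestable

    def test_missing_propagates_to_codes(self):
        coding = code_genotypes([-1, 1, 0], "quantitative")
        assert np.isnan(coding.codes[0])

    def test_qualitative_is_indicator_of_quantitative(self):
        g = [0, 1, 2, -1, 1]
        qual = code_genotypes(g, "qualitative").codes
        quant = code_genotypes(g, "quantitative").codes
        defined = ~np.isnan(quant)
        np.testing.assert_array_equal(qual[defined], (quant[defined] >= 1).astype(float))


class TestContingency:
    def test_hand_tally(self):
        table = build_contingency([1, 1, 0, 0], [1, 0, 1, 0])
        np.testing.assert_array_equal(table, [[1, 1], [1, 1]])

    def test_shapes_by_model(self):
        qual = build_contingency([0, 1, 0, 1], [1, 0, 1, 0])
        assert qual.shape == (2, 2)
        quant = build_contingency([0, 1, 2, 0, 1, 2], [1, 0, 1, 0, 1, 0])
        assert quant.shape == (3, 2)

    def test_total_conserved_and_missing_excluded(self):
        codes = [0, 1, np.nan, 1]
        statuses = [1, 0, 1, np.nan]
        table = build_contingency(codes, statuses)
        assert table.sum() == 2

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([np.nan], [1.0])


class TestFisherExact:
    def test_zero_margin_gives_one(self):
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_2x2_against_enumeration_and_scipy(self):
        table = [[3, 1], [1, 3]]
        p = fisher_exact(table)
        assert p == pytest.approx(34 / 70, rel=1e-9)  # hand enumeration
        assert p == pytest.approx(stats.fisher_exact(table)[1], rel=1e-9)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_3x2_freeman_halton_against_enumeration(self):
        table = [[1, 2], [2, 1], [3, 0]]
        assert fisher_exact(table) == pytest.approx(fisher_oracle(table), rel=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=6, max_size=6))
    def test_random_3x2_tables_match_oracle(self, cells):
        table = np.array(cells).reshape(3, 2)
        assert fisher_exact(table) == pytest.approx(fisher_oracle(table), rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    def test_random_2x2_tables_match_scipy(self, cells):
        table = np.array(cells).reshape(2, 2)
        assert fisher_exact(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-7, abs=1e-12
        )

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[1.5, 2.0], [0.0, 1.0]]))


class TestRegression:
    def test_constant_magnitudes_flat_response(self):
        slope, p = regression_stage([0, 1, 2, 0], [1.0, 1.0, 1.0, 1.0])
        assert slope == 0.0 and p == 1.0

    def test_closed_form_least_squares(self):
        # hand normal equations: Sxx = 4, Sxy = 1 -> slope 0.25
        slope, p = regression_stage([0, 1, 2, 0, 1, 2], [0.0, 0.3, 0.6, 0.1, 0.4, 0.5])
        assert slope == pytest.approx(0.25, rel=1e-12)
        assert p == pytest.approx(0.0017919834849, rel=1e-8)

    def test_matches_scipy_linregress(self, rng):
        x = rng.integers(0, 3, 30).astype(float)
        y = 0.3 * x + rng.normal(0, 0.2, 30)
        slope, p = regression_stage(x, y)
        ref = stats.linregress(x, y)
        assert slope == pytest.approx(ref.slope, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_perfect_fit_flagged_zero_p(self):
        with pytest.warns(UserWarning):
            slope, p = regression_stage([0, 1, 2], [0.0, 0.5, 1.0])
        assert slope == pytest.approx(0.5) and p == 0.0

    def test_constant_code_rejected(self):
        with pytest.raises(ValueError):
            regression_stage([1, 1, 1], [0.0, 0.5, 1.0])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            regression_stage([0, 1], [0.0, 1.0])


class TestKruskalWallis:
    def test_hand_ranked_two_groups(self):
        # ranks 1..6: H = 12/42 * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 3.857142857
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(27 / 7, 1), rel=1e-10)

    def test_all_equal_gives_zero(self):
        assert kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3], []])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_two_group_p_equals_wilcoxon_normal_approximation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=16), rng.normal(size=16)
        _h, p_kw = kruskal_wallis([a, b])
        p_w = stats.ranksums(a, b).pvalue
        assert p_kw == pytest.approx(p_w, abs=1e-6)


class TestCascade:
    def test_all_neutral_statuses_yield_no_fisher_passes(self):
        cfg = SimulationConfig(n_patients=32, n_genes=20, n_snps=40, cn_noise_sd=0.01, seed=3)
        cohort = simulate_cohort(cfg)
        records = run_cascade(
            cohort.genotypes_normal, cohort.snp_gene_map, cn_diff=cohort.cn_diff
        )
        # |CN_dif| never reaches 0.3 at noise SD 0.01, so every pair is skipped
        assert len(records) == 0

    def test_planted_qualitative_effect_survives_all_stages(self, planted_cohort):
        _cfg, cohort = planted_cohort
        retained, _ = filter_snps(cohort.genotypes_normal)
        records = run_cascade(
            cohort.genotypes_normal,
            cohort.snp_gene_map,
            cn_diff=cohort.cn_diff,
            retained_snps=retained,
        )
        hit = records[
            (records["snp_id"] == "snp00001") & (records["direction"] == "amplification")
        ]
        assert (hit["stage_passed"] == "kw").any()

    def test_planted_survivor_verified_by_direct_recomputation(self, planted_cohort):
        """Recompute each stage of the planted SNP's record from raw matrices."""
        _cfg, cohort = planted_cohort
        records = run_cascade(
            cohort.genotypes_normal, cohort.snp_gene_map, cn_diff=cohort.cn_diff
        )
        rec = records[
            (records["snp_id"] == "snp00001")
            & (records["direction"] == "amplification")
            & (records["model"] == "qualitative")
        ].iloc[0]
        codes = code_genotypes(cohort.genotypes_normal.loc["snp00001"], "qualitative").codes
        mags = cohort.cn_diff.loc["gene0001"].to_numpy()
        modified = (mags >= 0.3).astype(float)
        assert fisher_exact(build_contingency(codes, modified)) == pytest.approx(rec["fisher_p"])
        slope, reg_p = regression_stage(codes, mags)
        assert reg_p == pytest.approx(rec["regression_p"])
        _h, kw_p = kruskal_wallis([mags[codes == 0], mags[codes == 1]])
        assert kw_p == pytest.approx(rec["kw_p"])

    def test_stage_pvalues_gated_on_previous_stage(self, null_cohort):
        _cfg, cohort = null_cohort
        records = run_cascade(
            cohort.genotypes_normal, cohort.snp_gene_map,
            cn_diff=cohort.cn_diff, beta_diff=cohort.beta_diff,
        )
        failed_fisher = records[records["fisher_p"] >= 0.01]
        assert failed_fisher["regression_p"].isna().all()
        assert failed_fisher["kw_p"].isna().all()

    def test_summary_counts_monotone_non_increasing(self, planted_cohort):
        _cfg, cohort = planted_cohort
        records = run_cascade(
            cohort.genotypes_normal, cohort.snp_gene_map,
            cn_diff=cohort.cn_diff, beta_diff=cohort.beta_diff,
        )
        counts = stage_summary(records)
        assert (counts["fisher"] >= counts["regression"]).all()
        assert (counts["regression"] >= counts["kw"]).all()

    def test_summary_matches_independent_cross_tabulation(self, planted_cohort):
        _cfg, cohort = planted_cohort
        records = run_cascade(
            cohort.genotypes_normal, cohort.snp_gene_map, cn_diff=cohort.cn_diff
        )
        counts = stage_summary(records)
        amp = records[records["direction"] == "amplification"]
        expected_fisher = amp.loc[amp["fisher_p"] < 0.01, "snp_id"].nunique()
        row = counts[(counts["layer"] == "cnv") & (counts["direction"] == "amplification")]
        assert int(row["fisher"].iloc[0]) == expected_fisher
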