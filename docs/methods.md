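# Methods

`regsnp` implements an integrated association analysis for paired
tumor/normal cohorts whose goal is to find *regulatory SNPs*: germline
variants whose genotype predicts a somatic modification (copy-number change
or methylation change) at a gene, with a concordant downstream expression
change. This note records the statistical procedure, the generative model of
the synthetic cohorts, and the numerical and design choices that were
genuinely open.

## The analysis procedure

**Differential expression.** Expression matrices (log2 intensity scale,
genes x patients) are quantile-normalized — every column is forced onto the
per-rank across-column means; ties within a column receive the mean of the
reference values over their rank range — and each gene is tested with a
paired t-test on tumor minus normal values. `t = mean(d) / (sd(d)/sqrt(n))`
with `n-1` degrees of freedom; pairs with a missing value are dropped;
zero-variance difference vectors make the statistic undefined, which is
reported (NaN) rather than silently removed, and such genes are never
selected. The default selection threshold is `p < 1e-9`, which is stricter
than the Bonferroni bound `alpha/m` for any genome-scale `m`
(`0.05 / 54,675 = 9.14e-7`). The up/down split is summarized with integer
percentages.

**Modification calls.** Per gene and patient, the copy-number difference
`CN_dif` (tumor minus matched normal, copy-number units) is called
*amplified* when `CN_dif >= 0.3`, *deleted* when `CN_dif <= -0.3`, else
*neutral*; the methylation beta difference is called *hyper* at `>= 0.25`,
*hypo* at `<= -0.25`, else *unchanged*. Boundaries are inclusive ("at
least"). An absolute copy number of 2.3/1.7 against a diploid baseline is
the same rule up to the offset of 2.

**Segmentation (optional, marker-level input).** When gene-level `CN_dif`
must be derived from ordered marker-level differences, a deliberately simple
recursive binary splitting stands in for proprietary array-suite
segmentation. Within a region, the candidate breakpoint with the largest
mean gap (computed from cumulative sums, so each level is O(n)) is accepted
only if (i) both flanks hold at least `min_markers = 100` markers, (ii) the
Welch two-sample t-test across the split has `p <= 0.001`, and (iii) the
signal-to-noise ratio — operationalized as |mean difference| / pooled SD,
since no standard definition exists for this context — is `>= 0.3`. Flat
regions (zero pooled variance) are never split unless the means differ.
Genes take the length-weighted mean of overlapping segment means (or the
direct mean of in-interval markers when segmentation is skipped); 0-based
half-open coordinates throughout; strand is ignored because dosage and
methylation differences are strand-free. *Known limitation:* because the
flank rule is enforced at split time, a shifted block shorter than
`min_markers` that sits inside a long flat baseline can still be absorbed
into an accepted longer segment whose mean is diluted but nonzero; the rule
guarantees only that no reported segment has fewer than `min_markers`
markers, not that sub-minimum events leave no trace.

**SNP QC.** Minor allele frequency is computed from non-missing
normal-tissue calls over `2n` chromosomes and is always `min(freq, 1-freq)`.
Hardy-Weinberg equilibrium uses the exact conditional test (enumerate all
heterozygote counts compatible with the observed minor-allele total; sum the
probabilities of configurations no more likely than the observed one) —
exact rather than chi-square because the target cohort size is 32, where
asymptotics are unreliable. The retention rule is `MAF >= 0.01` and
`HWE p > 0.05`. Bowker's test of symmetry on the 3x3 normal x tumor
genotype table checks for systematic somatic allele shifts:
`chi2 = sum_{i<j} (n_ij - n_ji)^2 / (n_ij + n_ji)` over informative
off-diagonal pairs; by default df counts the informative pairs
(`n_ij + n_ji > 0`), with the textbook fixed `df = 3` as an option. QC uses
germline calls because hereditary alleles are the biomarkers of interest.

**Association cascade.** Each QC-passing SNP is tested against its host gene
(the gene it is assigned to in the SNP-to-gene map), in each layer
(CNV, methylation), each direction (amplification/deletion, hyper/hypo) and
each coding model:

* *qualitative*: 0/1 carrier indicator of the tested allele (dominant
  model); *quantitative*: 0/1/2 allele count (additive model). The tested
  allele defaults to the minor allele and is configurable; monomorphic
  codings are flagged untestable and skipped.
* Stage 1 — Fisher's exact test on the code-level x (modified, not-modified)
  table: 2x2 for the qualitative model, up to 3x2 (Freeman-Halton) for the
  quantitative model. "Not modified" pools every other status; the pooling
  is configurable in principle but no alternative is implemented because the
  trichotomy leaves no other natural choice. The two-sided p sums the
  probabilities of all margin-preserving tables whose (multivariate)
  hypergeometric probability is at most the observed one, with a relative
  tie tolerance of 1e-7. Implemented by direct enumeration with cached
  log-binomials; results are cached by margins, which makes genome-scale
  scans cheap because tables recur massively at n = 32.
* Stage 2 — ordinary least squares of the modification magnitude (`CN_dif`
  or delta-beta) on the code, two-sided t-test on the slope with `n-2` df.
  Constant magnitudes return (slope 0, p 1) — a flat response is no
  association; an exact fit (zero residual variance, nonzero slope) is
  reported as p = 0 with a warning.
* Stage 3 — Kruskal-Wallis on magnitudes grouped by code level,
  tie-corrected, chi-square reference with k-1 df; for two groups this is
  the two-sided Wilcoxon rank-sum test under the normal approximation
  (verified to 1e-6 in the tests). All-identical values give H = 0, p = 1.

Stages gate each other: each statistic is computed only if the previous
stage passed its threshold (default 0.01 at every stage). A gene-direction
pair with no modified or no unmodified patient is skipped (Fisher would be
degenerate). In the survivor summary a SNP counts once per direction if it
passes under either coding model, so counts are monotone non-increasing
along the cascade. Raw thresholds (no multiplicity correction) are the
default because the procedure is a screening cascade; the per-stage gating
itself is the false-positive control.

**Expression linkage.** Each full-cascade survivor's SNP grouping is tested
against per-patient expression log-ratios (tumor minus normal): Wilcoxon
rank-sum for two groups (exact for small tie-free samples via
`mannwhitneyu(method="auto")`), Kruskal-Wallis for three, at `p < 0.05`.
Note the deliberate asymmetry with stage 3: the cascade's Kruskal-Wallis op
uses the chi-square form so the documented rank-sum equivalence holds
exactly, while the linkage test prefers the exact small-sample null.
When both coding models survived, the qualitative grouping (two groups,
simpler) is reported. Concordance compares the sign of the carriers' median
log-ratio (median, not mean, to match the rank-based testing) with the
direction expected under the dosage / promoter-repression model:
amplification and hypomethylation push expression up (+1), deletion and
hypermethylation push it down (-1). Agreement is '+', opposition '-', an
exactly zero median is 'undetermined', as is any non-significant test.

## The synthetic cohort generator

The generator emulates the paired design at desk scale; defaults are the
study conditions and are not tuned per experiment.

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 32 | tumor/normal pairs |
| `n_genes`, `n_snps` | 500, 2000 | feature panel |
| `maf_range` | (0.05, 0.5) | per-SNP MAF drawn uniformly; a common-variant range typical of SNPs retained on a genotyping array after the MAF >= 0.01 filter |
| `somatic_flip_rate` | 0.001 | per-call probability that the tumor genotype moves uniformly to a different genotype; tumor/normal discordance is rare and directionless, so Bowker stays null |
| `cn_noise_sd` | 0.15 | Gaussian noise on `CN_dif`, half the 0.3 calling threshold |
| `beta_noise_sd` | 0.10 | Gaussian noise on delta-beta (clipped to [-1, 1]); beta arrays are less noisy than CN ratios |
| `expr_cn_coupling` | 1.0 | log2-ratio per copy-number unit (positive) |
| `expr_meth_coupling` | 1.0 | log2-ratio per beta unit, applied with a negative sign |
| `expr_noise_sd` | 0.5 | Gaussian noise on the log-ratio and the normal baseline |
| `expr_baseline` | 8.0 | normal-tissue log2 intensity level |
| `missing_rate` | 0 | optional missing-call rate per tissue |

Germline genotypes are drawn from HWE proportions (p^2, 2pq, q^2); planted
effects add `delta x code(driving SNP)` to a gene's `CN_dif` or delta-beta
(one driving SNP per gene by default; multiple effects are additive; a
planted SNP that comes out monomorphic is flagged in the truth table).
Expression is `log-ratio = cn_coupling*CN_dif - meth_coupling*dbeta +
DE shift + noise`, with `expr_tumor = expr_normal + log-ratio`. Fixing the
seed fixes every layer bit-for-bit (a single `numpy` Generator drives all
stages in a fixed order).

**What the generator does not model** — and therefore what passing tests do
not establish about real arrays: probe-level intensity structure and
normalization artifacts, linkage disequilibrium between SNPs (each SNP is
independent), tumor purity and subclonality, spatially correlated CN noise
along chromosomes, non-Gaussian heavy-tailed measurement error, and the
beta-value's bounded heteroscedastic noise (Gaussian-then-clip is used; the
clip only matters for implausibly large planted effects). The noise model of
the original measurements is unknown; Gaussian is this package's assumption.

## Numerical choices and degenerate inputs

* Exact-test tie comparisons use a relative tolerance (1e-7 for Fisher,
  1e-12 for HWE) so that floating-point jitter cannot drop a tied table from
  the tail sum.
* Fisher with a zero row or column margin returns p = 1 (single attainable
  table).
* The HWE test works with the rarer allele internally, making it invariant
  to homozygote label swaps; probabilities are computed with log-gamma and
  renormalized, so no factorial overflow at any n used here.
* `quantile_normalize` refuses missing values (the upstream pairing logic
  owns missingness); a single column is returned unchanged.
* Segmentation on fewer than `min_markers` markers warns and returns one
  segment; candidate split confirmation uses Welch-Satterthwaite df.
* Regression requires >= 3 complete patients and a non-constant code;
  cascade records propagate NaN p-values (never treated as passing).

## Problem sizes

Tests and the acceptance script run the full procedure at the cohort scale
the package targets (32 pairs) with panels of 60-2,000 SNPs and 50-500
genes, 5-20 replicate seeds for calibration and power measurements, 10,000
simulated SNPs for HWE calibration, and exhaustive enumeration over all 2x2
and 3x2 contingency tables with total count <= 20 for the Fisher oracle
check. These sizes give binomial standard errors comfortably below the
margins being asserted while keeping a full run in the low minutes on one
core.

## Known limitations

* Host-gene pairing only: every SNP is tested against the single gene it is
  mapped to; trans effects and flanking windows are out of scope (a window
  option would only change the SNP-to-gene map, which the caller supplies).
* The segmentation stand-in reproduces acceptance criteria, not any
  commercial tool's exact boundaries; see the smearing caveat above.
* Raw thresholds mean the cascade's family-wise error is controlled only by
  stage gating; Benjamini-Hochberg across pairs is a natural extension but
  is not the default because the reference procedure used raw thresholds.
* The concordance convention (amplification up, hypermethylation down, etc.)
  is a biological prior, not a fitted quantity; discordant '-' hits are
  reported, not suppressed.
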