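# regsnp

Regulatory-SNP discovery in paired tumor/normal cohorts.

Tumor transcriptomes are notoriously irreproducible across cohorts; changes
at the DNA level are more stable. `regsnp` implements an integrated screen
for **regulatory SNPs** — germline variants whose genotype predicts a
somatic genetic modification (a copy-number change or a methylation change)
at a gene, and whose modification drives a concordant change in that gene's
expression. It is aimed at analysts working with matched tumor/normal
designs (array or sequencing-derived gene-level summaries) who want a
transparent, fully testable implementation of the cascade, plus a synthetic
cohort generator with planted ground truth for validating every stage.

## The procedure

For a cohort of $n$ tumor/normal pairs:

1. **Differential expression** — quantile normalization, then a paired
   t-test per gene on tumor minus normal log2 intensities,
   $t = \bar d / (s_d/\sqrt n)$, selecting genes at $p < 10^{-9}$ (stricter
   than the Bonferroni bound $\alpha/m$).
2. **Modification calls** — per gene and patient, CNV status from the
   copy-number difference $\mathrm{CN_{dif}}$ (amplified $\ge 0.3$, deleted
   $\le -0.3$) and methylation status from the beta difference
   $\Delta\beta$ (hyper $\ge 0.25$, hypo $\le -0.25$). Gene-level
   $\mathrm{CN_{dif}}$ can be derived from ordered marker-level data by a
   simplified recursive segmentation honoring the classic acceptance rules
   ($\ge 100$ consecutive markers, split $p \le 0.001$, SNR $\ge 0.3$).
3. **SNP QC** — retain SNPs with MAF $\ge 0.01$ and exact Hardy-Weinberg
   $p > 0.05$ (germline calls); Bowker's symmetry test flags systematic
   tumor/normal genotype shifts.
4. **Association cascade** — per SNP-gene pair, layer, direction and coding
   model (carrier 0/1 or allele count 0/1/2): Fisher's exact test on the
   code $\times$ status table (2$\times$2 or 3$\times$2 Freeman-Halton),
   then OLS of the modification magnitude on the code, then Kruskal-Wallis
   on magnitudes by code group — each gated at $p < 0.01$.
5. **Expression linkage** — survivors are tested for grouped expression
   change (rank-sum / Kruskal-Wallis, $p < 0.05$) and classified
   concordant (`+`) when the carriers' median log-ratio matches the
   expected direction (amplification and hypomethylation up; deletion and
   hypermethylation down).

Full statistical details are in [docs/methods.md](docs/methods.md).

## Worked example

The `analysis/` scripts run the whole screen on a synthetic cohort with
known ground truth (32 pairs, 500 genes, 2,000 SNPs; 8 planted CNV SNPs, 6
planted methylation SNPs, 30 planted DE genes):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_differential_expression.py
...
python analysis/06_expression_linkage.py
```

Step 02 prints

```
30 genes selected at p < 1e-9 (vs Bonferroni threshold 0.05/500 = 0.0001)
  22 down (73%), 8 up (27%)
  recovered 30/30 planted DE genes
```

— every planted differentially expressed gene is recovered, with the
down-dominant split the generator planted. Step 06 prints the final
survivor counts and linked SNPs:

```
      layer     direction  fisher  regression  kw  expression_linked  concordant
        cnv amplification       4           4   4                  4           4
        cnv      deletion       4           4   4                  4           4
methylation         hyper       3           3   3                  2           2
methylation          hypo       3           3   3                  1           1

11 expression-linked SNPs (results/linked_snps.tsv):
      layer     direction  gene_id   snp_id   expr_p concordance
        cnv amplification gene0001 snp00001 0.002414           +
        ...
planted SNPs among linked: 11; concordant '+': 100%
```

All 14 planted modification SNPs survive the three-stage cascade (counts are
monotone non-increasing across stages); 11 also show a significant grouped
expression change, every one concordant with its planted direction. The
expression-linkage stage is the lossiest — exactly the behavior expected of
a rank test on 32 patients with moderate coupling.

The same functionality is exposed as a CLI for file-based workflows:

```sh
regsnp simulate --out cohort/ --seed 5
regsnp run-all --cohort cohort/ --out results/
regsnp qc-snps --genotypes cohort/genotypes_normal.tsv --out qc.tsv
```

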