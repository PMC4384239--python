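#!/usr/bin/env python
"""Generate the study-condition synthetic cohort.

32 tumor/normal pairs, 500 genes, 2,000 SNPs. Planted ground truth: four
amplification and four deletion SNPs (|delta| = 0.8 copy-number units), three
hypermethylation and three hypomethylation SNPs (|delta beta| = 0.5), and 30
differentially expressed genes of which 22 are down-regulated — the
down-dominant pattern expected of this tumor type. Everything downstream
(02-06) reads the cohort directory written here.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from regsnp import PlantedEffect, SimulationConfig, simulate_cohort

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"


def build_config(seed: int = 20150324 % 2**31) -> SimulationConfig:
    cnv = [PlantedEffect(f"snp{i + 1:05d}", f"gene{i + 1:04d}", 0.8, "qualitative") for i in range(4)]
    cnv += [PlantedEffect(f"snp{i + 5:05d}", f"gene{i + 5:04d}", -0.8, "qualitative") for i in range(4)]
    meth = [PlantedEffect(f"snp{i + 9:05d}", f"gene{i + 9:04d}", 0.5, "qualitative") for i in range(3)]
    meth += [PlantedEffect(f"snp{i + 12:05d}", f"gene{i + 12:04d}", -0.5, "qualitative") for i in range(3)]
    de = [(f"gene{i + 101:04d}", -1.5) for i in range(22)] + [(f"gene{i + 123:04d}", 1.5) for i in range(8)]
    return SimulationConfig(
        n_patients=32, n_genes=500, n_snps=2000,
        planted_cnv_effects=cnv, planted_meth_effects=meth, planted_de_effects=de,
        seed=seed,
    )


def main() -> None:
    cfg = build_config()
    cohort = simulate_cohort(cfg)
    cohort.to_dir(OUT)
    cfg.to_yaml(OUT / "config.yaml")
    n_mono = int(cohort.truth["monomorphic"].sum())
    print(f"cohort written to {OUT}")
    print(f"  {cfg.n_snps} SNPs x {cfg.n_patients} patients, {cfg.n_genes} genes")
    print(f"  planted: {len(cfg.planted_cnv_effects)} CNV SNPs, "
          f"{len(cfg.planted_meth_effects)} methylation SNPs, "
          f"{len(cfg.planted_de_effects)} DE genes ({n_mono} planted SNPs monomorphic)")


if __name__ == "__main__":
    main()
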