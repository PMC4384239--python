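"""The paired tumor/normal cohort container and its plain-text I/O.

All layers are pandas DataFrames with patients as columns. Genotypes are coded
as minor-allele counts: 0 = homozygous major, 1 = heterozygous, 2 = homozygous
minor, -1 = missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_LAYER_FILES = {
    "genotypes_normal": "genotypes_normal.tsv",
    "genotypes_tumor": "genotypes_tumor.tsv",
    "cn_diff": "cn_diff.tsv",
    "beta_diff": "beta_diff.tsv",
    "expr_tumor": "expr_tumor.tsv",
    "expr_normal": "expr_normal.tsv",
}


@dataclass
class PairedCohort:
    """Per-patient matrices for one paired tumor/normal cohort.

    ``truth`` records planted effects and is present only for synthetic
    cohorts; real cohorts carry ``truth=None``.
    """

    genotypes_normal: pd.DataFrame
    genotypes_tumor: pd.DataFrame
    cn_diff: pd.DataFrame
    beta_diff: pd.DataFrame
    expr_tumor: pd.DataFrame
    expr_normal: pd.DataFrame
    snp_gene_map: pd.Series  # index snp_id -> gene_id
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        patients = list(self.genotypes_normal.columns)
        for name in ("genotypes_tumor", "cn_diff", "beta_diff", "expr_tumor", "expr_normal"):
            df = getattr(self, name)
            if list(df.columns) != patients:
                raise ValueError(f"patient columns of {name} differ from genotypes_normal")
        if not self.genotypes_normal.index.equals(self.genotypes_tumor.index):
            raise ValueError("tumor and normal genotype matrices index different SNPs")
        for name in ("cn_diff", "expr_tumor", "expr_normal"):
            if not getattr(self, name).index.equals(self.cn_diff.index):
                raise ValueError(f"gene rows of {name} differ from cn_diff")
        beta = self.beta_diff.to_numpy(float)
        ok = np.isnan(beta) | ((beta >= -1) & (beta <= 1))
        if not ok.all():
            raise ValueError("beta_diff entries must lie in [-1, 1]")

    @property
    def patients(self) -> list[str]:
        return list(self.genotypes_normal.columns)

    @property
    def n_patients(self) -> int:
        return self.genotypes_normal.shape[1]

    def to_dir(self, out_dir: str | os.PathLike) -> None:
        """Write all layers as TSV matrices (patients as columns)."""
        os.makedirs(out_dir, exist_ok=True)
        for attr, fname in _LAYER_FILES.items():
            df = getattr(self, attr)
            fmt = None if attr.startswith("genotypes") else "%.6g"
            df.to_csv(os.path.join(out_dir, fname), sep="\t", float_format=fmt)
        self.snp_gene_map.rename("gene_id").rename_axis("snp_id").to_csv(
            os.path.join(out_dir, "snp_gene_map.tsv"), sep="\t"
        )
        if self.truth is not None:
            self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)

    @classmethod
    def from_dir(cls, in_dir: str | os.PathLike) -> "PairedCohort":
        layers = {}
        for attr, fname in _LAYER_FILES.items():
            path = os.path.join(in_dir, fname)
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"missing cohort layer {fname} in {in_dir}; expected a TSV matrix "
                    "with feature ids in the first column and patient ids as header"
                )
            df = pd.read_csv(path, sep="\t", index_col=0)
            if attr.startswith("genotypes"):
                df = df.astype(int)
            layers[attr] = df
        map_path = os.path.join(in_dir, "snp_gene_map.tsv")
        snp_gene = pd.read_csv(map_path, sep="\t", index_col=0)["gene_id"]
        truth_path = os.path.join(in_dir, "truth.tsv")
        truth = pd.read_csv(truth_path, sep="\t") if os.path.exists(truth_path) else None
        return cls(snp_gene_map=snp_gene, truth=truth, **layers)


def read_genotype_tsv(path) -> pd.DataFrame:
    """Read a SNP x patient genotype matrix coded 0/1/2 with NA for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(
            f"genotype file {path} is empty; expected rows = SNPs, columns = patients, "
            "cells coded 0/1/2/NA"
        )
    values = df.to_numpy(float)
    bad = ~(np.isnan(values) | np.isin(values, [0.0, 1.0, 2.0, -1.0]))
    if bad.any():
        raise ValueError(f"genotype file {path} contains calls outside 0/1/2/NA")
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


_GENO_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: pd.DataFrame, path) -> None:
    """Export genotypes as a minimal unphased VCF (GT field only).

    Coordinates are placeholders (one SNP per position on a single contig);
    REF/ALT encode the major/minor allele abstractly as A/B.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.columns) + "\n")
        for pos, (snp_id, row) in enumerate(genotypes.iterrows(), start=1):
            gts = "\t".join(_GENO_TO_GT[int(v)] for v in row)
            fh.write(f"1\t{pos}\t{snp_id}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> pd.DataFrame:
    """Import genotypes from a VCF (GT only); requires cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows = [], []
    for variant in vcf:
        if len(variant.ALT) > 1:
            raise ValueError(f"multi-allelic record {variant.ID} not supported")
        ids.append(variant.ID)
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        g = variant.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    return pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
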