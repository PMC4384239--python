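"""Configuration objects for the synthetic cohort generator and the pipeline.

The simulator emulates a paired tumor/normal design: germline genotypes in
Hardy-Weinberg equilibrium, rare somatic genotype discordance, SNP-allele-driven
shifts in per-gene copy-number difference (CN_dif, tumor minus normal) and in
methylation beta-difference, and expression log-ratios coupled positively to
copy number and negatively to methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ParameterError(ValueError):
    """Raised when a configuration value is outside its valid range."""


QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"
MODELS = (QUALITATIVE, QUANTITATIVE)


@dataclass(frozen=True)
class PlantedEffect:
    """A planted SNP -> modification effect.

    ``delta`` is the shift (copy-number units or beta units) added per unit of
    the SNP code of the driving SNP under ``model`` (carrier indicator for
    qualitative, allele count for quantitative).
    """

    snp_id: str
    gene_id: str
    delta: float
    model: str = QUALITATIVE

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown coding model: {self.model!r}")


@dataclass
class SimulationConfig:
    """All generator parameters for one synthetic paired cohort.

    Defaults describe the paired design the package targets: 32 tumor/normal
    pairs, common germline variants, rare somatic genotype flips, and
    modification noise on the scale of the calling thresholds (0.3 copy-number
    units, 0.25 beta units).
    """

    n_patients: int = 32
    n_genes: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    somatic_flip_rate: float = 0.001
    missing_rate: float = 0.0
    planted_cnv_effects: list[PlantedEffect] = field(default_factory=list)
    planted_meth_effects: list[PlantedEffect] = field(default_factory=list)
    cn_noise_sd: float = 0.15
    beta_noise_sd: float = 0.1
    expr_cn_coupling: float = 1.0
    expr_meth_coupling: float = 1.0
    planted_de_effects: list[tuple[str, float]] = field(default_factory=list)
    expr_noise_sd: float = 0.5
    expr_baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_cnv_effects = [_as_effect(e) for e in self.planted_cnv_effects]
        self.planted_meth_effects = [_as_effect(e) for e in self.planted_meth_effects]
        self.planted_de_effects = [tuple(e) for e in self.planted_de_effects]
        self.maf_range = tuple(self.maf_range)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if self.n_genes < 1 or self.n_snps < 1:
            raise ParameterError("n_genes and n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must lie within (0, 0.5]: {self.maf_range}")
        for name in ("somatic_flip_rate", "missing_rate"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ParameterError(f"{name} must be a probability in [0, 1]: {p}")
        for name in ("cn_noise_sd", "beta_noise_sd", "expr_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        gene_ids = set(gene_names(self.n_genes))
        snp_ids = set(snp_names(self.n_snps))
        for eff in self.planted_cnv_effects + self.planted_meth_effects:
            if eff.snp_id not in snp_ids:
                raise ParameterError(f"planted effect references unknown SNP {eff.snp_id}")
            if eff.gene_id not in gene_ids:
                raise ParameterError(f"planted effect references unknown gene {eff.gene_id}")
        for gene_id, _shift in self.planted_de_effects:
            if gene_id not in gene_ids:
                raise ParameterError(f"planted DE effect references unknown gene {gene_id}")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["maf_range"] = list(self.maf_range)
        data["planted_de_effects"] = [list(e) for e in self.planted_de_effects]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _as_effect(e) -> PlantedEffect:
    if isinstance(e, PlantedEffect):
        return e
    if isinstance(e, dict):
        return PlantedEffect(**e)
    return PlantedEffect(*e)


def patient_names(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def gene_names(n: int) -> list[str]:
    return [f"gene{i + 1:04d}" for i in range(n)]


def snp_names(n: int) -> list[str]:
    return [f"snp{i + 1:05d}" for i in range(n)]


@dataclass
class PipelineConfig:
    """Thresholds for the full pipeline; defaults are the study's values.

    de_p: paired-t selection threshold; cn/beta: modification-call thresholds;
    maf/hwe: SNP QC; t1..t3: cascade stage thresholds (Fisher, regression,
    Kruskal-Wallis); expr_p: expression-linkage rank-test threshold.
    """

    de_p: float = 1e-9
    cn: float = 0.3
    beta: float = 0.25
    maf: float = 0.01
    hwe: float = 0.05
    t1: float = 0.01
    t2: float = 0.01
    t3: float = 0.01
    expr_p: float = 0.05
    models: Sequence[str] = MODELS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_p", "maf", "hwe", "t1", "t2", "t3", "expr_p"):
            v = getattr(self, name)
            if not (0 < v <= 1) and name != "maf":
                raise ParameterError(f"{name} must be in (0, 1]: {v}")
        if not (0 <= self.maf <= 0.5):
            raise ParameterError(f"maf must be in [0, 0.5]: {self.maf}")
        if self.cn <= 0 or self.beta <= 0:
            raise ParameterError("cn and beta thresholds must be positive")
        for m in self.models:
            if m not in MODELS:
                raise ParameterError(f"unknown coding model: {m!r}")
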