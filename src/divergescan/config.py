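"""Simulation configuration and deterministic random-stream management.

A single :class:`SimulationConfig` drives every synthetic component: the two
genotype genomes, the expression count matrix (2 genotypes x 4 stages x 3
replicates), the methylome cytosine reports (2 genotypes x 2 stages x 3
replicates), the chloroplast conversion control and the CDS ortholog pairs.
One global seed fully determines all outputs; each generator draws from a
named sub-stream spawned from that seed so individual components can be
regenerated independently without perturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

GENOTYPES = ("HAL2", "FIL2")
STAGES_EXPR = ("D1", "D2", "D3", "D4")
STAGES_METH = ("D1", "D4")
CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_KINDS = ("promoter", "utr5", "cds", "intron", "utr3")
INTERGENIC = "intergenic"

# Named sub-streams; the index is the spawn key so adding a stream never
# shifts the draws of an existing one.
_STREAMS = (
    "genome_HAL2",
    "genome_FIL2",
    "counts",
    "methylome",
    "cds",
    "chloroplast",
    "feature_table",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: per-context methylation baselines of
    0.66/0.49/0.031 (CG/CHG/CHH), a 500-bp promoter window, a 2x4x3 expression
    design and a 2x2x3 methylome design, and a bisulfite conversion failure
    rate of 0.025 (i.e. a 97.5% conversion rate).
    """

    n_genes: int = 150
    n_chromosomes: int = 2
    gene_length_range: tuple[int, int] = (900, 3000)
    exons_per_gene_range: tuple[int, int] = (1, 4)
    promoter_len: int = 500
    intergenic_gap_range: tuple[int, int] = (800, 2500)
    n_replicates: int = 3
    baseline_meth: tuple[float, float, float] = (0.66, 0.49, 0.031)
    site_noise_sd: float = 0.05
    coverage_mean: float = 20.0
    coverage_dispersion: float = 0.3
    frac_dmr_features: float = 0.10
    dmr_delta: float = 0.30
    frac_deg: tuple[float, float, float] = (0.10, 0.20, 0.10)
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    conversion_failure_rate: float = 0.025
    chloroplast_n_sites: int = 2000
    chloroplast_coverage_mean: float = 20.0
    frac_kaks_positive: float = 0.10
    n_cds_pairs: int = 100
    cds_n_codons_range: tuple[int, int] = (80, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        proportions = {
            "frac_dmr_features": self.frac_dmr_features,
            "conversion_failure_rate": self.conversion_failure_rate,
            "frac_kaks_positive": self.frac_kaks_positive,
            **{f"frac_deg[{i}]": f for i, f in enumerate(self.frac_deg)},
            **{f"baseline_meth[{i}]": b for i, b in enumerate(self.baseline_meth)},
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} must lie in [0, 1]")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 3 * self.exons_per_gene_range[1]:
            raise ConfigurationError(
                "gene_length_range infeasible: genes need >= 3 bp per exon"
            )
        if self.exons_per_gene_range[0] < 1:
            raise ConfigurationError("genes need at least one exon")
        if self.n_replicates < 2:
            raise ConfigurationError("each design cell needs >= 2 replicates")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if not 0 <= self.conversion_failure_rate < 1:
            raise ConfigurationError("conversion_failure_rate must lie in [0, 1)")

    # -- random streams -----------------------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        """Return the deterministic generator for a named sub-stream."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown random stream {stream!r}")
        key = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in (
            "gene_length_range",
            "exons_per_gene_range",
            "intergenic_gap_range",
            "baseline_meth",
            "frac_deg",
            "library_size_range",
            "cds_n_codons_range",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def expression_design(config: SimulationConfig):
    """Sample table for the RNA-seq design (genotype x stage x replicate)."""
    import pandas as pd

    rows = [
        {
            "sample": f"{g}_{s}_r{r + 1}",
            "genotype": g,
            "stage": s,
            "replicate": r + 1,
        }
        for g in GENOTYPES
        for s in STAGES_EXPR
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows)


def methylome_design(config: SimulationConfig):
    """Sample table for the bisulfite design (genotype x stage x replicate)."""
    import pandas as pd

    rows = [
        {
            "sample": f"{g}_{s}_r{r + 1}",
            "genotype": g,
            "stage": s,
            "replicate": r + 1,
        }
        for g in GENOTYPES
        for s in STAGES_METH
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows)
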