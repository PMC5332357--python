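"""Simulation configuration and seeded random-stream derivation.

A single integer seed controls every stochastic stage of the synthetic-data
generator.  Each stage (genome construction, EMS mutation draw, pooled read
depths, F2 marker genotypes, natural-panel genotypes, qPCR Ct noise) draws
from its own :class:`numpy.random.Generator`, derived from the master seed
with a fixed per-stage spawn key, so any stage can be regenerated in
isolation and the full run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed spawn keys, one independent random stream per simulation stage.
STAGE_KEYS = {
    "genome": 0,
    "ems": 1,
    "depths": 2,
    "markers": 3,
    "panel": 4,
    "ct": 5,
    "proteins": 6,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic forward-genetics study.

    Defaults emulate the study design this package models: a recessive
    EMS-induced locus mapped with a 42-plant homozygous-recessive F2 bulk
    sequenced at ~30x, an EMS density of 0.3 mutations/kb, a 578-plant F2
    population and a 412-line natural panel, on a 7-chromosome genome
    reduced to desk scale (500 kb per chromosome).

    The genetic map uses a constant rate of ``cm_per_kb`` (default 0.2,
    i.e. ~100 cM per 500-kb chromosome).  The scale-down preserves the
    genetic length of a chromosome rather than the per-bp crossover rate:
    linkage structure along each synthetic chromosome then behaves like a
    real chromosome's, which is what the bulk-sequencing signal depends on.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 7
    chrom_length_bp: int = 500_000
    genes_per_chromosome: int = 3
    gene_cds_codons: int = 300          # non-causal genes: 900-bp CDS
    gene_n_exons: int = 3
    intron_length_bp: int = 200
    # causal locus
    causal_chrom_index: int = 4         # 5th chromosome, as in the study
    causal_effect: str = "stop_gain"
    # EMS mutagenesis
    ems_rate_per_kb: float = 0.3
    # pooled sequencing
    bulk_size: int = 42                 # homozygous-recessive F2 plants in the pool
    mean_depth: float = 30.0            # reads per site, Poisson mean
    cm_per_kb: float = 0.2              # physical->genetic map scale
    n_background_snps: int = 300        # parental SNPs shared by mutant line and WT parent
    # populations
    n_f2: int = 578
    n_panel: int = 412

    def __post_init__(self) -> None:
        if self.ems_rate_per_kb <= 0:
            raise ValueError("ems_rate_per_kb must be > 0")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "genes_per_chromosome",
            "gene_cds_codons",
            "gene_n_exons",
            "intron_length_bp",
            "n_f2",
            "n_panel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.cm_per_kb <= 0:
            raise ValueError("cm_per_kb must be positive")
        if not 0 <= self.causal_chrom_index < self.n_chromosomes:
            raise ValueError("causal_chrom_index out of range")
        if self.causal_effect != "stop_gain":
            raise ValueError("only stop_gain causal effects are supported")

    def rng(self, stage: str) -> np.random.Generator:
        """Return the dedicated random generator for one simulation stage."""
        if stage not in STAGE_KEYS:
            raise KeyError(f"unknown simulation stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(STAGE_KEYS[stage],))
        return np.random.default_rng(ss)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]
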