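"""Configuration objects and seeded RNG-stream derivation.

A single integer seed drives every stochastic stage. Each stage derives its
own independent :class:`numpy.random.Generator` from the global seed and a
stage name, so adding a stage never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields

import numpy as np

__all__ = ["SimulationConfig", "rng_for", "seed_for"]


def seed_for(seed: int, stream: str) -> np.random.SeedSequence:
    """Derive a named, reproducible seed sequence from a global seed."""
    return np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stream.encode())])


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """A generator for one named stage, fully determined by (seed, stream)."""
    return np.random.default_rng(seed_for(seed, stream))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the sampling design the pipeline targets: six species,
    five individuals per sex, gonad and spleen sampled from every individual.
    Gene- and site-level scales are desk-sized but keep the statistical
    structure (SFS shape contrasts, tissue/sex expression bias, Brownian
    trait evolution) that the downstream analyses assume.

    Parameters
    ----------
    n_species:
        Number of species on the phylogeny.
    n_individuals_per_sex:
        Diploid individuals sampled per sex per species.
    n_genes:
        Genes per species (orthologous across species, shared ids).
    sites_per_gene:
        Polymorphic-candidate sites simulated per gene.
    balancing_fraction:
        Fraction of non-tissue-biased genes whose SFS is enriched for
        intermediate frequencies (ongoing balancing selection).
    balancing_strength:
        Intensity of that enrichment; 0 = neutral 1/j spectrum.
    mean_depth:
        Mean Poisson sequencing depth per site per individual.
    error_rate:
        Per-base sequencing error probability, in [0, 0.5).
    inbreeding_f:
        Per-individual inbreeding coefficient used when drawing genotypes.
    nb_dispersion:
        Negative-binomial dispersion of read counts (0 -> Poisson limit).
    tissue_bias_lfc, sex_bias_lfc:
        Planted log2 fold changes for tissue- and sex-biased genes.
    bm_sigma2:
        Brownian-motion rate for trait evolution (trait^2 per unit branch).
    coupling:
        Slope linking species dichromatism to the species-level balancing
        intensity applied to gonad-biased genes; 0 decouples them.
    seed:
        Global seed; every stream is derived from it by stage name.
    """

    n_species: int = 6
    n_individuals_per_sex: int = 5
    n_genes: int = 200
    sites_per_gene: int = 30
    balancing_fraction: float = 0.3
    balancing_strength: float = 4.0
    mean_depth: float = 10.0
    error_rate: float = 0.01
    inbreeding_f: float = 0.0
    nb_dispersion: float = 0.1
    tissue_bias_lfc: float = 3.0
    sex_bias_lfc: float = 2.0
    bm_sigma2: float = 1.0
    coupling: float = 0.0
    seed: int = 0
    # composition of the simulated gene universe
    gonad_biased_fraction: float = 0.20
    spleen_biased_fraction: float = 0.15
    sex_biased_fraction: float = 0.25
    z_fraction: float = 0.10
    immune_fraction: float = 0.05
    coupling_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_species", "n_individuals_per_sex", "n_genes", "sites_per_gene"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "balancing_fraction",
            "inbreeding_f",
            "gonad_biased_fraction",
            "spleen_biased_fraction",
            "sex_biased_fraction",
            "z_fraction",
            "immune_fraction",
        ):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.balancing_strength < 0:
            raise ValueError("balancing_strength must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.gonad_biased_fraction + self.spleen_biased_fraction >= 1.0:
            raise ValueError("tissue-biased fractions must sum to < 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    def rng(self, stream: str) -> np.random.Generator:
        return rng_for(self.seed, stream)
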