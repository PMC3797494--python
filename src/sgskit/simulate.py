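"""Spatially explicit forward-time isolation-by-distance simulator.

Generates genotype + coordinate datasets with known gene-dispersal variance
and density so the whole analysis chain can be validated against theory:
under two-dimensional isolation by distance, Sp ~= 1/Nb with Wright's
neighborhood size Nb = 4*pi*De*sigma^2.

Model: a constant-size population of N diploid adults on a square torus,
non-overlapping generations. Each offspring draws a mother uniformly at
random, is placed at the mother's position plus axial Gaussian(0, sigma_seed)
displacement (wrapped), and draws a father (a different adult) with
probability proportional to a Gaussian pollen kernel of scale sigma_pollen
centered on the mother. The composite axial gene-dispersal variance is
therefore sigma^2 = sigma_seed^2 + sigma_pollen^2 / 2: pollen moves paternal
genes only, and every gene then disperses as seed. Since every adult has the
same expected reproductive success, Ne ~= N and the truth record uses
De = D (census density).

Microsatellite mutation follows the stepwise model by default (+-1 repeat);
a k-alleles model is available. Null-allele corruption, applied to the
sampled reads only, turns each gene copy independently into a non-amplifying
allele with the given rate: heterozygote (null, x) reads as homozygote
(x, x), (null, null) reads as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset, SpatialCoordinates

__all__ = [
    "IBDSimParams",
    "simulate_ibd_population",
    "expected_sp",
    "SpTableSimParams",
    "simulate_sp_meta_table",
]


@dataclass
class IBDSimParams:
    """Parameters of the torus isolation-by-distance simulation.

    Defaults emulate the sampling regime of low-density tropical tree
    populations: tens of individuals at a few per hectare, ~12 microsatellite
    loci, dispersal limited relative to the study extent.
    """

    habitat_side: float = 1000.0  # meters (square torus)
    census_density_D: float = 4.0  # individuals / hectare
    sigma_seed: float = 20.0  # axial SD of seed dispersal, m
    sigma_pollen: float = 21.213203435596427  # axial SD of pollen, m (15*sqrt(2))
    n_loci: int = 12
    mutation_model: str = "stepwise"  # or "k_alleles"
    mutation_rate: float = 1e-3  # per gamete per locus
    n_founder_alleles: int = 10
    n_generations: int = 200
    sample_size: int = 100
    null_allele_rate: float = 0.0
    dioecious: bool = False
    rng_seed: int = 0

    @property
    def n_adults(self) -> int:
        return int(round(self.habitat_side**2 * self.census_density_D / 10_000.0))

    @property
    def sigma_composite(self) -> float:
        """Axial gene-dispersal SD: sigma^2 = sigma_seed^2 + sigma_pollen^2/2."""
        return float(np.sqrt(self.sigma_seed**2 + self.sigma_pollen**2 / 2.0))

    def validate(self) -> None:
        if self.n_adults < self.sample_size:
            raise ValueError(
                f"sample_size {self.sample_size} exceeds adult population "
                f"{self.n_adults} (= side^2 * D / 1e4)"
            )
        if self.n_loci < 1 or self.n_generations < 1:
            raise ValueError("need >= 1 locus and >= 1 generation")
        if not (0 <= self.null_allele_rate < 1):
            raise ValueError("null_allele_rate must be in [0, 1)")
        if self.mutation_model not in ("stepwise", "k_alleles"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")
        if max(self.sigma_seed, self.sigma_pollen) >= self.habitat_side / 2:
            warnings.warn("dispersal scale >= half the habitat: effectively panmictic")


def expected_sp(de_per_ha: float, sigma: float) -> float:
    """Theoretical Sp = 1/Nb = 1/(4*pi*De*sigma^2) under 2-D IBD.

    ``de_per_ha`` is the effective density in individuals per hectare and
    ``sigma`` the axial gene-dispersal SD in meters.
    """
    if de_per_ha <= 0 or sigma <= 0:
        raise ValueError("De and sigma must be strictly positive")
    de_m2 = de_per_ha / 10_000.0
    return 1.0 / (4.0 * np.pi * de_m2 * sigma**2)


def _torus_sq_dist(pos: np.ndarray, side: float) -> np.ndarray:
    """Squared torus distances between all rows of (N, 2) positions."""
    d = np.abs(pos[:, None, :] - pos[None, :, :])
    d = np.minimum(d, side - d)
    return (d**2).sum(axis=2)


def _mutate(gametes: np.ndarray, params: IBDSimParams, rng: np.random.Generator,
            founder_states: np.ndarray) -> np.ndarray:
    hit = rng.random(gametes.shape) < params.mutation_rate
    if not hit.any():
        return gametes
    if params.mutation_model == "stepwise":
        steps = rng.choice((-1, 1), size=int(hit.sum()))
        gametes[hit] = gametes[hit] + steps
    else:
        gametes[hit] = rng.choice(founder_states, size=int(hit.sum()))
    return gametes


def simulate_ibd_population(
    params: IBDSimParams,
) -> tuple[GenotypeDataset, SpatialCoordinates, dict]:
    """Run the forward simulation and sample a mapped genotype dataset.

    Returns (genotypes, coordinates, truth) where ``truth`` records the
    composite sigma, effective density, and the theoretical Sp they imply.
    Fixing ``rng_seed`` makes the output fully reproducible.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    N, L, side = params.n_adults, params.n_loci, params.habitat_side
    founder_states = 100 + np.arange(params.n_founder_alleles)
    pos = rng.uniform(0, side, size=(N, 2))
    alleles = rng.choice(founder_states, size=(N, L, 2)).astype(np.int64)
    sex = None
    if params.dioecious:
        sex = np.zeros(N, dtype=bool)  # False = female, True = male
        sex[rng.permutation(N)[: N // 2]] = True
    two_sp2 = 2.0 * params.sigma_pollen**2
    for _gen in range(params.n_generations):
        sq = _torus_sq_dist(pos, side)
        with np.errstate(under="ignore"):
            W = np.exp(-sq / two_sp2)
        np.fill_diagonal(W, 0.0)  # no selfing
        if params.dioecious:
            W[:, ~sex] = 0.0  # fathers must be male
            mother_pool = np.flatnonzero(~sex)
            mothers = rng.choice(mother_pool, size=N)
        else:
            mothers = rng.integers(N, size=N)
        rows = W[mothers]
        csum = np.cumsum(rows, axis=1)
        totals = csum[:, -1]
        u = rng.random(N) * totals
        fathers = np.minimum((csum < u[:, None]).sum(axis=1), N - 1)
        dead = totals <= 0
        if dead.any():  # pollen kernel underflowed: fall back to uniform choice
            pool = np.flatnonzero(sex) if params.dioecious else np.arange(N)
            fathers[dead] = rng.choice(pool, size=int(dead.sum()))
        locus_idx = np.arange(L)[None, :]
        maternal = alleles[mothers[:, None], locus_idx, rng.integers(2, size=(N, L))]
        paternal = alleles[fathers[:, None], locus_idx, rng.integers(2, size=(N, L))]
        maternal = _mutate(maternal, params, rng, founder_states)
        paternal = _mutate(paternal, params, rng, founder_states)
        alleles = np.stack([maternal, paternal], axis=2)
        pos = np.mod(
            pos[mothers] + rng.normal(0, params.sigma_seed, size=(N, 2)), side
        )
        if params.dioecious:
            sex = np.zeros(N, dtype=bool)
            sex[rng.permutation(N)[: N // 2]] = True
    take = rng.choice(N, size=params.sample_size, replace=False)
    reads = alleles[take].copy()
    if params.null_allele_rate > 0:
        null = rng.random(reads.shape) < params.null_allele_rate
        one_null = null[..., 0] ^ null[..., 1]
        # the amplifying copy is read twice (false homozygote)
        amplifying = np.where(null[..., 0], reads[..., 1], reads[..., 0])
        reads[one_null, 0] = amplifying[one_null]
        reads[one_null, 1] = amplifying[one_null]
        both_null = null.all(axis=2)
        reads[both_null] = 0
    ids = [f"ind{k:04d}" for k in range(params.sample_size)]
    genotypes = GenotypeDataset(
        individual_ids=ids,
        loci=[f"L{j + 1:02d}" for j in range(L)],
        calls=reads,
        population_labels=["sim"] * params.sample_size,
    )
    coords = SpatialCoordinates(
        individual_ids=ids, x=pos[take, 0], y=pos[take, 1], wrap=side
    )
    sigma = params.sigma_composite
    truth = {
        "n_adults": N,
        "sigma_seed": params.sigma_seed,
        "sigma_pollen": params.sigma_pollen,
        "sigma_composite": sigma,
        "de_per_ha": params.census_density_D,  # Ne ~= N here, so De = D
        "de_m2": params.census_density_D / 10_000.0,
        "expected_sp": expected_sp(params.census_density_D, sigma),
        "null_allele_rate": params.null_allele_rate,
    }
    return genotypes, coords, truth


@dataclass
class SpTableSimParams:
    """Log-normal group parameters for simulated species-level Sp tables.

    ``groups`` maps group label -> (n_species, mean of log Sp, SD of log Sp).
    """

    groups: dict = field(default_factory=lambda: {
        "monoecy": (12, np.log(0.008), 0.8),
        "dioecy": (11, np.log(0.016), 0.8),
    })
    rng_seed: int = 0

    def validate(self) -> None:
        for name, (n, _mu, sd) in self.groups.items():
            if n < 2:
                raise ValueError(f"group {name!r}: need n >= 2")
            if sd < 0:
                raise ValueError(f"group {name!r}: log-SD must be >= 0")


def simulate_sp_meta_table(params: SpTableSimParams) -> pd.DataFrame:
    """Draw a species-level Sp table with log-normal within-group variation.

    Returns a DataFrame with columns species, sexual_system, sp — the shape
    the comparative analysis consumes.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    rows = []
    for name, (n, mu, sd) in params.groups.items():
        sp = np.exp(rng.normal(mu, sd, size=n))
        for k, value in enumerate(sp):
            rows.append(
                {"species": f"{name}_sp{k + 1}", "sexual_system": name, "sp": value}
            )
    return pd.DataFrame(rows)
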