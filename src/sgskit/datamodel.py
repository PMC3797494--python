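"""Core containers: genotypes, coordinates, and density information.

Genotypes are diploid codominant calls (e.g. microsatellite repeat sizes)
stored as an ``(n_individuals, n_loci, 2)`` integer array. Allele code 0 is
the missing sentinel; a call with any missing allele is treated as fully
missing. Within-call allele order carries no information and is normalized
to ascending order on construction, so datasets differing only in within-call
order compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "SpatialCoordinates",
    "DensityInfo",
    "JoinReport",
    "ValidationError",
    "validate_dataset",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


def _as_labels(values: Optional[Sequence[str]], n: int, what: str) -> Optional[list]:
    if values is None:
        return None
    out = [str(v) for v in values]
    if len(out) != n:
        raise ValidationError(f"{what}: expected {n} labels, got {len(out)}")
    return out


@dataclass
class GenotypeDataset:
    """Diploid codominant genotypes for a set of mapped individuals.

    Parameters
    ----------
    individual_ids
        Unique labels, one per individual.
    loci
        Ordered locus names.
    calls
        Integer array ``(n, n_loci, 2)`` of allele codes; 0 marks missing.
        The within-call pair is unordered and is normalized on construction.
    population_labels, cluster_labels
        Optional per-individual labels (cluster labels stand in for an
        external spatial-clustering assignment).
    """

    individual_ids: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    calls: np.ndarray = None
    population_labels: Optional[list] = None
    cluster_labels: Optional[list] = None

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.loci = [str(l) for l in self.loci]
        n, L = len(self.individual_ids), len(self.loci)
        if n < 1 or L < 1:
            raise ValidationError("need at least 1 individual and 1 locus")
        if len(set(self.individual_ids)) != n:
            dupes = sorted({i for i in self.individual_ids if self.individual_ids.count(i) > 1})
            raise ValidationError(f"duplicated individual id(s): {dupes}")
        if len(set(self.loci)) != L:
            raise ValidationError("duplicated locus names")
        calls = np.asarray(self.calls, dtype=np.int64)
        if calls.shape != (n, L, 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match ({n}, {L}, 2)"
            )
        if (calls < 0).any():
            raise ValidationError("allele codes must be non-negative integers")
        # half-missing calls become fully missing; then sort within pair
        half = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
        calls[half] = MISSING
        calls = np.sort(calls, axis=2)
        self.calls = calls
        self.population_labels = _as_labels(self.population_labels, n, "population_labels")
        self.cluster_labels = _as_labels(self.cluster_labels, n, "cluster_labels")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, n_loci)``; True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def genotyped_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    def subset_individuals(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            individual_ids=[self.individual_ids[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            population_labels=(
                [self.population_labels[i] for i in idx] if self.population_labels else None
            ),
            cluster_labels=(
                [self.cluster_labels[i] for i in idx] if self.cluster_labels else None
            ),
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeDataset":
        keep = [self.loci.index(l) for l in loci]
        return GenotypeDataset(
            individual_ids=list(self.individual_ids),
            loci=[self.loci[j] for j in keep],
            calls=self.calls[:, keep].copy(),
            population_labels=self.population_labels,
            cluster_labels=self.cluster_labels,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.population_labels == other.population_labels
            and self.cluster_labels == other.cluster_labels
        )


@dataclass
class SpatialCoordinates:
    """Planar per-individual positions in meters (projected; Euclidean).

    ``wrap`` marks a periodic square domain of that side length (simulated
    torus habitats); distances then use the minimum-image convention. Field
    data leaves it unset.
    """

    individual_ids: list = field(default_factory=list)
    x: np.ndarray = None
    y: np.ndarray = None
    wrap: Optional[float] = None

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            dupes = sorted({i for i in self.individual_ids if self.individual_ids.count(i) > 1})
            raise ValidationError(f"duplicated coordinate id(s): {dupes}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValidationError("x/y must be 1-D and match the number of ids")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("coordinates must be finite")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise distances in meters, shape ``(n, n)``.

        Euclidean, or minimum-image when the domain is periodic (``wrap``).
        """
        dx = np.abs(self.x[:, None] - self.x[None, :])
        dy = np.abs(self.y[:, None] - self.y[None, :])
        if self.wrap is not None:
            dx = np.minimum(dx, self.wrap - dx)
            dy = np.minimum(dy, self.wrap - dy)
        return np.hypot(dx, dy)

    def subset(self, indices: Sequence[int]) -> "SpatialCoordinates":
        idx = list(indices)
        return SpatialCoordinates(
            individual_ids=[self.individual_ids[i] for i in idx],
            x=self.x[idx].copy(),
            y=self.y[idx].copy(),
            wrap=self.wrap,
        )


@dataclass
class DensityInfo:
    """Census density and its conversion to effective density.

    ``effective_density`` follows De = D * (Ne/N); the conventional field
    default Ne/N = 1/4 gives De = D/4 for natural plant populations.
    """

    census_density_D: float  # individuals / hectare
    ne_over_n: float = 0.25

    def __post_init__(self):
        if not (self.census_density_D > 0 and self.ne_over_n > 0):
            raise ValidationError("density and Ne/N ratio must be strictly positive")

    @property
    def effective_density_ha(self) -> float:
        """Effective density in individuals per hectare."""
        return self.census_density_D * self.ne_over_n

    @property
    def effective_density_m2(self) -> float:
        """Effective density in individuals per square meter."""
        return self.effective_density_ha / 10_000.0


@dataclass
class JoinReport:
    n_joined: int
    dropped_genotype_ids: list
    dropped_coordinate_ids: list


def validate_dataset(
    genotypes: GenotypeDataset,
    coords: SpatialCoordinates,
    min_individuals: int = 10,
) -> tuple[GenotypeDataset, SpatialCoordinates, JoinReport]:
    """Inner-join genotypes and coordinates on individual id.

    Individuals present in only one input are dropped (reported). Fewer than
    ``min_individuals`` joined individuals is a hard error: spatial
    autocorrelation on a handful of pairs is meaningless.
    """
    gid = set(genotypes.individual_ids)
    cid = set(coords.individual_ids)
    common = gid & cid
    if not common:
        raise ValidationError("no overlap between genotype and coordinate ids")
    keep_g = [i for i, ind in enumerate(genotypes.individual_ids) if ind in common]
    joined_g = genotypes.subset_individuals(keep_g)
    order = {ind: k for k, ind in enumerate(coords.individual_ids)}
    keep_c = [order[ind] for ind in joined_g.individual_ids]
    joined_c = coords.subset(keep_c)
    report = JoinReport(
        n_joined=len(common),
        dropped_genotype_ids=sorted(gid - common),
        dropped_coordinate_ids=sorted(cid - common),
    )
    if report.n_joined < min_individuals:
        raise ValidationError(
            f"only {report.n_joined} individuals after join; "
            f"need at least {min_individuals} for spatial analysis"
        )
    return joined_g, joined_c, report
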