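"""Fine-scale spatial genetic structure: kinship, correlograms, Sp, sigma.

The analysis chain is: pairwise Loiselle kinship F_ij -> equal-count distance
classes -> permutation correlogram -> OLS regression of F_ij on ln(distance)
-> Sp = -b_log / (1 - F_1) -> neighborhood size Nb = 1/Sp -> iterative
gene-dispersal (sigma) estimation from Nb = 4*pi*De*sigma^2 with the
regression restricted to the (sigma, 20*sigma) distance range.

Conventions that matter when comparing across studies: the regression uses
the natural logarithm of distance and is fit over all pairwise points (class
means serve visualization only); zero-distance pairs are excluded and
counted; F_1 is the mean kinship of the first equal-count distance class,
whose upper bound is always reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import DensityInfo, GenotypeDataset, SpatialCoordinates

__all__ = [
    "KinshipMatrix",
    "loiselle_kinship_matrix",
    "DistanceClasses",
    "build_distance_classes",
    "correlogram_with_permutation",
    "kinship_log_regression",
    "RegressionResult",
    "sp_statistic",
    "neighborhood_size",
    "SigmaEstimate",
    "sigma_iterative",
    "SGSResult",
    "sgs_analysis",
]


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship with per-pair co-genotyped locus counts."""

    values: np.ndarray  # (n, n); diagonal unused; NaN where undefined
    n_shared_loci: np.ndarray  # (n, n) int

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


def loiselle_kinship_matrix(g: GenotypeDataset) -> KinshipMatrix:
    """Loiselle et al. (1995) kinship coefficient for every individual pair.

    For allele a at locus l, let p_ila in {0, 1/2, 1} be individual i's
    dosage, p_la the sample frequency over the n_l genotyped individuals.
    Then

        F_ij = [ sum_la (p_ila - p_la)(p_jla - p_la)
                 + sum_la p_la (1 - p_la) / (n_l - 1) ]
               / sum_la p_la (1 - p_la)

    with sums restricted, for each pair, to the polymorphic loci genotyped
    in both individuals; the multilocus value is the ratio of sums, which
    weights loci by their polymorphism. Pairs sharing no such locus get NaN.
    """
    n = g.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    genotyped = g.genotyped_mask()
    any_poly = False
    for j, _locus in enumerate(g.loci):
        mask = genotyped[:, j]
        n_l = int(mask.sum())
        if n_l < 2:
            continue
        pairs = g.calls[:, j]
        alleles = np.unique(pairs[mask].ravel())
        if alleles.size < 2:
            continue
        any_poly = True
        # dosage matrix (n, n_alleles); rows of missing individuals are zeroed
        dosage = (
            (pairs[:, 0, None] == alleles[None, :]).astype(float)
            + (pairs[:, 1, None] == alleles[None, :])
        ) / 2.0
        p_bar = dosage[mask].mean(axis=0)
        centered = np.where(mask[:, None], dosage - p_bar[None, :], 0.0)
        s_l = float(np.sum(p_bar * (1 - p_bar)))
        both = np.outer(mask, mask)
        num += centered @ centered.T + (s_l / (n_l - 1)) * both
        den += s_l * both
        shared += both.astype(np.int64)
    if not any_poly:
        raise ValueError("no polymorphic locus; kinship undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(values, np.nan)
    return KinshipMatrix(values=values, n_shared_loci=shared)


@dataclass
class DistanceClasses:
    """Equal-pair-count distance classes over the analyzable pairs.

    ``pair_i``/``pair_j`` index the included pairs (i < j, d > 0, kinship
    defined); ``pair_class`` assigns each to a class; ``bounds`` holds the
    k+1 class boundaries in meters.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_dist: np.ndarray
    pair_class: np.ndarray
    bounds: np.ndarray
    n_zero_distance: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.bounds) - 1

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.pair_class, minlength=self.n_classes)

    def class_mean_dist(self) -> np.ndarray:
        out = np.full(self.n_classes, np.nan)
        for k in range(self.n_classes):
            sel = self.pair_class == k
            if sel.any():
                out[k] = self.pair_dist[sel].mean()
        return out


def build_distance_classes(
    coords: SpatialCoordinates,
    n_classes: int = 7,
    min_pairs: int = 100,
    kinship: Optional[KinshipMatrix] = None,
) -> DistanceClasses:
    """Quantile (equal-pair-count) binning of pairwise distances.

    Pairs at distance 0 (co-located stems) are excluded and counted, as are
    pairs whose kinship is undefined when a matrix is supplied. If the pair
    total cannot support ``n_classes`` classes of ``min_pairs`` each, the
    class count is reduced with a warning.
    """
    dmat = coords.distance_matrix()
    iu, ju = np.triu_indices(coords.n_individuals, k=1)
    d = dmat[iu, ju]
    usable = d > 0
    n_zero = int((~usable).sum())
    if kinship is not None:
        usable &= np.isfinite(kinship.values[iu, ju])
    iu, ju, d = iu[usable], ju[usable], d[usable]
    n_pairs = d.size
    if n_pairs == 0:
        raise ValueError("no pairs with positive distance")
    if np.ptp(d) == 0:
        warnings.warn("all pairwise distances identical; single distance class")
        n_classes = 1
    elif n_pairs < n_classes * min_pairs:
        reduced = max(1, n_pairs // min_pairs)
        warnings.warn(
            f"{n_pairs} pairs support only {reduced} classes of >= {min_pairs} "
            f"pairs (requested {n_classes}); reducing"
        )
        n_classes = reduced
    order = np.argsort(d, kind="stable")
    chunks = np.array_split(order, n_classes)
    pair_class = np.empty(n_pairs, dtype=np.int64)
    for k, chunk in enumerate(chunks):
        pair_class[chunk] = k
    bounds = np.empty(n_classes + 1)
    bounds[0] = d.min()
    for k, chunk in enumerate(chunks):
        bounds[k + 1] = d[chunk].max()
    return DistanceClasses(
        pair_i=iu, pair_j=ju, pair_dist=d, pair_class=pair_class,
        bounds=bounds, n_zero_distance=n_zero,
    )


def _permuted_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(perms, axis=1)


def correlogram_with_permutation(
    kinship: KinshipMatrix,
    coords: SpatialCoordinates,
    classes: DistanceClasses,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-class mean kinship with a location-permutation null.

    Permuting individual locations (equivalently, multilocus genotypes among
    locations) preserves the multiset of F_ij and only rewires which pairs
    fall in which class. Columns: class, d_lower, d_upper, n_pairs,
    mean_dist, mean_F, env_lo, env_hi (2.5/97.5 percentiles), p (two-sided,
    add-one corrected, deviation measured from the permutation grand mean).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    F = kinship.values
    n = kinship.n_individuals
    perms = _permuted_indices(n, n_perm, rng)
    rows = []
    grand = float(np.nanmean(F[classes.pair_i, classes.pair_j]))
    for k in range(classes.n_classes):
        sel = classes.pair_class == k
        if not sel.any():
            warnings.warn(f"distance class {k} empty after NA removal; dropped")
            continue
        i_k, j_k = classes.pair_i[sel], classes.pair_j[sel]
        obs = float(np.nanmean(F[i_k, j_k]))
        perm_means = np.nanmean(F[perms[:, i_k], perms[:, j_k]], axis=1)
        dev = abs(obs - grand)
        p = (np.sum(np.abs(perm_means - grand) >= dev) + 1) / (n_perm + 1)
        rows.append(
            {
                "class": k,
                "d_lower": classes.bounds[k],
                "d_upper": classes.bounds[k + 1],
                "n_pairs": int(sel.sum()),
                "mean_dist": float(classes.pair_dist[sel].mean()),
                "mean_F": obs,
                "env_lo": float(np.percentile(perm_means, 2.5)),
                "env_hi": float(np.percentile(perm_means, 97.5)),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    b_log: float
    r2: float
    f1: float
    p_value: float
    n_pairs: int
    n_zero_excluded: int
    first_class_upper: float


def kinship_log_regression(
    kinship: KinshipMatrix,
    coords: SpatialCoordinates,
    distance_range: Optional[tuple[float, float]] = None,
    classes: Optional[DistanceClasses] = None,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> RegressionResult:
    """OLS of pairwise F_ij on ln(distance) with a permutation test on b.

    The fit runs over all pairwise points in ``distance_range`` (natural
    log), never over class means. F_1 is the mean kinship of the first
    distance class (built with defaults if not supplied). The p-value for
    the slope permutes locations among individuals, two-sided, add-one.
    """
    if classes is None:
        classes = build_distance_classes(coords, kinship=kinship)
    d = classes.pair_dist
    in_range = np.ones(d.size, dtype=bool)
    if distance_range is not None:
        lo, hi = distance_range
        in_range = (d > lo) & (d <= hi)
    i_r, j_r, d_r = classes.pair_i[in_range], classes.pair_j[in_range], d[in_range]
    if np.unique(d_r).size < 3:
        raise ValueError("need >= 3 pairs with distinct distances in range")
    F = kinship.values
    y = F[i_r, j_r]
    x = np.log(d_r)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    b = float(np.sum(xc * y) / sxx)
    yc = y - y.mean()
    ss_tot = float(np.sum(yc**2))
    r2 = (b**2 * sxx / ss_tot) if ss_tot > 0 else np.nan
    # permutation null for b: relabel locations, keep the kinship multiset
    rng = np.random.default_rng(seed)
    n = kinship.n_individuals
    b_perm = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(1, d_r.size)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = _permuted_indices(n, m, rng)
        y_perm = F[perms[:, i_r], perms[:, j_r]]
        b_perm[done : done + m] = (y_perm @ xc) / sxx
        done += m
    p = float((np.sum(np.abs(b_perm) >= abs(b)) + 1) / (n_perm + 1))
    first = classes.pair_class == 0
    f1 = float(np.nanmean(F[classes.pair_i[first], classes.pair_j[first]]))
    return RegressionResult(
        b_log=b,
        r2=r2,
        f1=f1,
        p_value=p,
        n_pairs=int(d_r.size),
        n_zero_excluded=classes.n_zero_distance,
        first_class_upper=float(classes.bounds[1]),
    )


def sp_statistic(b_log: float, f1: float) -> float:
    """Sp = -b_log / (1 - F_1), the intensity of spatial genetic structure.

    b_log is the regression slope of kinship on ln(distance) and F_1 the
    mean kinship of the first distance class. Sp <= 0 means no positive
    structure; F_1 = 1 leaves Sp undefined.
    """
    if f1 == 1:
        raise ValueError("F_1 = 1: Sp undefined")
    return -b_log / (1.0 - f1)


def neighborhood_size(sp: float) -> float:
    """Wright's neighborhood size Nb = 1/Sp (requires Sp > 0)."""
    if sp <= 0:
        raise ValueError("neighborhood size requires Sp > 0 (positive SGS)")
    return 1.0 / sp


@dataclass
class SigmaEstimate:
    """Iterative gene-dispersal estimate (axial sigma, meters)."""

    sigma: float
    nb: float
    de_m2: float
    converged: bool
    n_iterations: int
    distance_range: tuple = (np.nan, np.nan)
    b_restricted: float = np.nan


def sigma_iterative(
    kinship: KinshipMatrix,
    coords: SpatialCoordinates,
    density: DensityInfo,
    classes: Optional[DistanceClasses] = None,
    max_iter: int = 100,
    rel_tol: float = 1e-3,
) -> SigmaEstimate:
    """Estimate axial gene-dispersal sigma from Nb = 4*pi*De*sigma^2.

    Starting from the slope over the full distance range, iterate:
    Nb = -(1 - F_1)/b over the active range, sigma = sqrt(Nb/(4*pi*De)),
    then restrict the active range to (sigma, 20*sigma) intersected with the
    data extent and refit, until sigma changes by less than ``rel_tol``
    (relative). A non-negative slope, or an active range covering fewer than
    3 distance classes, aborts with ``converged=False`` and sigma = NaN.
    """
    if classes is None:
        classes = build_distance_classes(coords, kinship=kinship)
    de = density.effective_density_m2
    d = classes.pair_dist
    extent = (float(d.min()), float(d.max()))
    F = kinship.values
    first = classes.pair_class == 0
    f1 = float(np.nanmean(F[classes.pair_i[first], classes.pair_j[first]]))
    class_lo = classes.bounds[:-1]
    class_hi = classes.bounds[1:]

    def slope(lo: float, hi: float) -> tuple[float, int]:
        sel = (d > lo) & (d <= hi)
        if sel.sum() < 3:
            return np.nan, int(sel.sum())
        x = np.log(d[sel])
        if np.unique(x).size < 2:
            return np.nan, int(sel.sum())
        y = F[classes.pair_i[sel], classes.pair_j[sel]]
        xc = x - x.mean()
        return float(np.sum(xc * y) / np.sum(xc**2)), int(sel.sum())

    lo, hi = 0.0, extent[1]
    sigma_old = np.nan
    b = np.nan
    for iteration in range(1, max_iter + 1):
        b, _n_used = slope(lo, hi)
        if not np.isfinite(b) or b >= 0:
            return SigmaEstimate(np.nan, np.nan, de, False, iteration, (lo, hi), b)
        nb = -(1.0 - f1) / b
        sigma = float(np.sqrt(nb / (4.0 * np.pi * de)))
        if np.isfinite(sigma_old) and abs(sigma - sigma_old) / sigma_old < rel_tol:
            return SigmaEstimate(sigma, nb, de, True, iteration, (lo, hi), b)
        sigma_old = sigma
        lo = max(sigma, extent[0] * 0.0)
        hi = min(20.0 * sigma, extent[1])
        n_classes_in = int(np.sum((class_hi > lo) & (class_lo < hi)))
        if n_classes_in < 3 or lo >= hi:
            return SigmaEstimate(np.nan, np.nan, de, False, iteration, (lo, hi), b)
    return SigmaEstimate(sigma_old, -(1.0 - f1) / b, de, False, max_iter, (lo, hi), b)


@dataclass
class SGSResult:
    """Full spatial-genetic-structure summary for one sample."""

    b_log: float
    r2: float
    f1: float
    sp: float
    nb: Optional[float]
    p_value: float
    n_pairs: int
    n_zero_excluded: int
    first_class_upper: float
    correlogram: pd.DataFrame = field(default_factory=pd.DataFrame)
    sigma: Optional[SigmaEstimate] = None


def sgs_analysis(
    g: GenotypeDataset,
    coords: SpatialCoordinates,
    density: Optional[DensityInfo] = None,
    n_classes: int = 7,
    min_pairs: int = 100,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> SGSResult:
    """Run the whole chain: kinship -> classes -> correlogram -> b, Sp, sigma."""
    kin = loiselle_kinship_matrix(g)
    classes = build_distance_classes(coords, n_classes, min_pairs, kinship=kin)
    corr = correlogram_with_permutation(kin, coords, classes, n_perm=n_perm, seed=seed)
    reg = kinship_log_regression(
        kin, coords, classes=classes, n_perm=n_perm, seed=seed
    )
    sp = sp_statistic(reg.b_log, reg.f1)
    nb = 1.0 / sp if sp > 0 else None
    sigma = None
    if density is not None and sp > 0:
        sigma = sigma_iterative(kin, coords, density, classes=classes)
    return SGSResult(
        b_log=reg.b_log,
        r2=reg.r2,
        f1=reg.f1,
        sp=sp,
        nb=nb,
        p_value=reg.p_value,
        n_pairs=reg.n_pairs,
        n_zero_excluded=reg.n_zero_excluded,
        first_class_upper=reg.first_class_upper,
        correlogram=corr,
        sigma=sigma,
    )
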