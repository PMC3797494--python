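"""Per-locus and multilocus diversity and inbreeding statistics.

Implements the standard toolkit for codominant markers: allele frequencies,
observed and Nei-unbiased expected heterozygosity, rarefied allelic richness,
Weir & Cockerham (1984) variance-component F-statistics with jackknife SEs,
a gene-copy permutation test for F_IS, and the Brookfield/Chakraborty null
allele estimators with a modified multilocus F_IS that excludes flagged loci.

Missing data policy: an individual missing at locus *l* is excluded from all
locus-*l* statistics; multilocus estimators are ratios of components summed
over loci, never means of per-locus ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .datamodel import GenotypeDataset

__all__ = [
    "allele_frequencies",
    "heterozygosities",
    "allelic_richness_rarefied",
    "wc_f_statistics",
    "FStatResult",
    "fis_inference",
    "null_allele_frequency",
    "NullAlleleEstimate",
    "multilocus_fis_excluding_null",
    "locus_summary_table",
]


def _locus_calls(g: GenotypeDataset, locus: str, subset: Optional[Sequence[int]] = None):
    """Non-missing (m, 2) allele pairs for one locus, optionally on a subset."""
    j = g.loci.index(locus)
    calls = g.calls[:, j] if subset is None else g.calls[list(subset), j]
    keep = ~(calls == 0).all(axis=1)
    return calls[keep]


def allele_frequencies(
    g: GenotypeDataset, locus: str, subset: Optional[Sequence[int]] = None
) -> pd.Series:
    """Sample allele frequencies over non-missing calls at one locus.

    Returns a Series indexed by allele code; ``.attrs['n']`` carries the
    number of genotyped individuals. An all-missing locus raises ValueError.
    """
    pairs = _locus_calls(g, locus, subset)
    if pairs.shape[0] == 0:
        raise ValueError(f"locus {locus!r}: no non-missing calls in subset")
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    freqs = pd.Series(counts / counts.sum(), index=alleles, name=locus)
    freqs.attrs["n"] = int(pairs.shape[0])
    return freqs


def heterozygosities(
    g: GenotypeDataset, locus: str, subset: Optional[Sequence[int]] = None
) -> tuple[float, float]:
    """(H_O, H_E) at one locus; H_E is Nei's unbiased estimator.

    H_E = (2n / (2n - 1)) * (1 - sum_a p_a^2) with n genotyped individuals.
    Requires n >= 2.
    """
    pairs = _locus_calls(g, locus, subset)
    n = pairs.shape[0]
    if n < 2:
        raise ValueError(f"locus {locus!r}: need >=2 genotyped individuals, have {n}")
    h_o = float(np.mean(pairs[:, 0] != pairs[:, 1]))
    _, counts = np.unique(pairs.ravel(), return_counts=True)
    p = counts / counts.sum()
    h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    return h_o, h_e


def allelic_richness_rarefied(allele_counts: Sequence[int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: A_R(g) = sum_a [1 - C(N - N_a, g) / C(N, g)]
    where N is the total number of sampled gene copies and N_a the count of
    allele a. ``g`` may not exceed N.
    """
    counts = np.asarray([c for c in allele_counts if c > 0], dtype=np.int64)
    if counts.size == 0:
        raise ValueError("no allele counts")
    if g < 1:
        raise ValueError("g must be >= 1")
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds total gene copies N={N}")
    total = 0.0
    for Na in counts:
        # C(N-Na, g)/C(N, g) as a stable product of ratios
        ratio = 1.0
        for k in range(g):
            num = N - Na - k
            if num <= 0:
                ratio = 0.0
                break
            ratio *= num / (N - k)
        total += 1.0 - ratio
    return total


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------


def _wc_locus_components(pop_pairs: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) components over alleles at one locus.

    ``pop_pairs`` holds one (n_i, 2) non-missing genotype array per
    population. Populations with n_i < 2 are dropped. With a single
    population the among-population component a is identically 0 and the
    within/between-individual split (b, c) still estimates f = F_IS.
    """
    pops = [p for p in pop_pairs if p.shape[0] >= 2]
    r = len(pops)
    if r == 0:
        return 0.0, 0.0, 0.0
    ns = np.array([p.shape[0] for p in pops], dtype=float)
    nbar = ns.mean()
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0
    A = B = C = 0.0
    if r > 1:
        nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    for allele in alleles:
        p_i = np.array([np.mean(p == allele) for p in pops])
        h_i = np.array([np.mean((p == allele).sum(axis=1) == 1) for p in pops])
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        hbar = float(np.sum(ns * h_i) / (r * nbar))
        if r > 1:
            s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
        c = hbar / 2.0
        A, B, C = A + a, B + b, C + c
    return A, B, C


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


@dataclass
class FStatResult:
    """Weir–Cockerham F-statistics with per-locus components.

    ``per_locus`` columns: locus, a, b, c, f, theta, fit. Multilocus values
    are ratios of summed components; jackknife SEs delete one locus at a time.
    """

    per_locus: pd.DataFrame
    f: float  # F_IS
    theta: float  # F_ST
    fit: float  # F_IT
    jackknife_se: dict = field(default_factory=dict)
    fis_p_value: Optional[float] = None


def _components_table(
    g: GenotypeDataset, labels: Sequence[str], subset: Optional[Sequence[int]]
) -> pd.DataFrame:
    idx = list(range(g.n_individuals)) if subset is None else list(subset)
    labels = [labels[i] for i in idx]
    groups = sorted(set(labels))
    rows = []
    for locus in g.loci:
        j = g.loci.index(locus)
        pop_pairs = []
        for grp in groups:
            members = [i for i, lab in zip(idx, labels) if lab == grp]
            calls = g.calls[members, j]
            pop_pairs.append(calls[~(calls == 0).all(axis=1)])
        a, b, c = _wc_locus_components(pop_pairs)
        rows.append(
            {
                "locus": locus,
                "a": a,
                "b": b,
                "c": c,
                "f": 1 - _ratio(c, b + c),
                "theta": _ratio(a, a + b + c),
                "fit": 1 - _ratio(c, a + b + c),
            }
        )
    return pd.DataFrame(rows)


def wc_f_statistics(
    g: GenotypeDataset,
    population_labels: Optional[Sequence[str]] = None,
    subset: Optional[Sequence[int]] = None,
) -> FStatResult:
    """Multilocus Weir–Cockerham f (F_IS), theta (F_ST) and F_IT.

    With one population only f is meaningful (theta is NaN). Jackknife-over-
    loci standard errors are reported when >= 2 informative loci exist.
    """
    labels = list(population_labels) if population_labels is not None else (
        g.population_labels or ["pop1"] * g.n_individuals
    )
    tab = _components_table(g, labels, subset)
    A, B, C = tab["a"].sum(), tab["b"].sum(), tab["c"].sum()
    result = FStatResult(
        per_locus=tab,
        f=1 - _ratio(C, B + C),
        theta=_ratio(A, A + B + C),
        fit=1 - _ratio(C, A + B + C),
    )
    informative = tab[(tab[["a", "b", "c"]].abs().sum(axis=1)) > 0]
    if len(informative) >= 2:
        jack_f, jack_t = [], []
        for locus in informative["locus"]:
            rest = tab[tab["locus"] != locus]
            Ar, Br, Cr = rest["a"].sum(), rest["b"].sum(), rest["c"].sum()
            jack_f.append(1 - _ratio(Cr, Br + Cr))
            jack_t.append(_ratio(Ar, Ar + Br + Cr))
        L = len(informative)
        fac = (L - 1) / L
        result.jackknife_se = {
            "f": float(np.sqrt(fac * np.sum((np.array(jack_f) - np.mean(jack_f)) ** 2))),
            "theta": float(
                np.sqrt(fac * np.sum((np.array(jack_t) - np.mean(jack_t)) ** 2))
            ),
        }
    return result


# ---------------------------------------------------------------------------
# F_IS permutation inference
# ---------------------------------------------------------------------------


def _fis_from_het_freqs(p: np.ndarray, h: np.ndarray, m: int) -> tuple[float, float]:
    """Summed (b, c) over alleles for one locus, from fixed allele
    frequencies ``p`` and heterozygote-carrier frequencies ``h``."""
    b = (m / (m - 1)) * (p * (1 - p) - ((2 * m - 1) / (4 * m)) * h)
    c = h / 2.0
    return float(b.sum()), float(c.sum())


def fis_inference(
    g: GenotypeDataset,
    subset: Optional[Sequence[int]] = None,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Multilocus F_IS and a two-sided permutation p-value.

    The null is built by shuffling gene copies among individuals within the
    subset, independently per locus (random union of gametes); F_IS is
    recomputed on each shuffle and p = (#{|F*| >= |F_obs|} + 1) / (n_perm + 1).
    Allele frequencies are invariant under the shuffle, so only heterozygote
    frequencies are recomputed — this keeps 10,000 permutations cheap.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    B_obs = C_obs = 0.0
    B_perm = np.zeros(n_perm)
    C_perm = np.zeros(n_perm)
    any_polymorphic = False
    for locus in g.loci:
        pairs = _locus_calls(g, locus, subset)
        m = pairs.shape[0]
        if m < 2:
            continue
        alleles, counts = np.unique(pairs.ravel(), return_counts=True)
        if alleles.size < 2:
            continue
        any_polymorphic = True
        p = counts / counts.sum()
        het = pairs[:, 0] != pairs[:, 1]
        h_obs = np.array(
            [np.mean(het & ((pairs == a).any(axis=1))) for a in alleles]
        )
        b, c = _fis_from_het_freqs(p, h_obs, m)
        B_obs, C_obs = B_obs + b, C_obs + c
        # vectorized shuffles: (n_perm, 2m) permutations of the gene copies
        flat = np.tile(pairs.ravel(), (n_perm, 1))
        flat = rng.permuted(flat, axis=1)
        shuffled = flat.reshape(n_perm, m, 2)
        het_p = shuffled[:, :, 0] != shuffled[:, :, 1]
        for a, pa in zip(alleles, p):
            carrier = het_p & (shuffled == a).any(axis=2)
            h_a = carrier.mean(axis=1)
            B_perm += (m / (m - 1)) * (pa * (1 - pa) - ((2 * m - 1) / (4 * m)) * h_a)
            C_perm += h_a / 2.0
    if not any_polymorphic:
        return np.nan, np.nan
    f_obs = 1 - C_obs / (B_obs + C_obs)
    f_perm = 1 - C_perm / (B_perm + C_perm)
    p_value = (np.sum(np.abs(f_perm) >= abs(f_obs)) + 1) / (n_perm + 1)
    return float(f_obs), float(p_value)


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------


@dataclass
class NullAlleleEstimate:
    frequency: float
    method: str
    flag: str = ""  # "no evidence" when the estimate is non-positive


def null_allele_frequency(
    h_e: float, h_o: float, method: str = "brookfield1"
) -> NullAlleleEstimate:
    """Null allele frequency from the heterozygote deficit at one locus.

    brookfield1: r = (H_E - H_O) / (1 + H_E)
    chakraborty: r = (H_E - H_O) / (H_E + H_O)

    Non-positive estimates are returned as-is with flag "no evidence";
    H_E = H_O = 0 is undefined (NaN).
    """
    if method == "brookfield1":
        r = (h_e - h_o) / (1 + h_e)
    elif method == "chakraborty":
        if h_e + h_o == 0:
            return NullAlleleEstimate(np.nan, method, "undefined")
        r = (h_e - h_o) / (h_e + h_o)
    else:
        raise ValueError(f"unknown null-allele method: {method!r}")
    if h_e == 0 and h_o == 0:
        return NullAlleleEstimate(np.nan, method, "undefined")
    return NullAlleleEstimate(float(r), method, "" if r > 0 else "no evidence")


def multilocus_fis_excluding_null(
    g: GenotypeDataset,
    flagged_loci: Sequence[str],
    subset: Optional[Sequence[int]] = None,
) -> tuple[float, float, float]:
    """Modified multilocus F_IS over loci not flagged for null alleles.

    Returns (F_IS, jackknife SE, two-sided normal-theory p). At least two
    loci must remain after exclusion.
    """
    retained = [l for l in g.loci if l not in set(flagged_loci)]
    if len(retained) < 2:
        raise ValueError("need >= 2 loci after excluding flagged loci")
    sub = g.subset_loci(retained)
    labels = ["all"] * sub.n_individuals
    res = wc_f_statistics(sub, population_labels=labels, subset=subset)
    se = res.jackknife_se.get("f", np.nan)
    if se and np.isfinite(se) and se > 0:
        z = res.f / se
        p = 2 * float(_stats.norm.sf(abs(z)))
    else:
        p = np.nan
    return res.f, se, p


def locus_summary_table(
    g: GenotypeDataset,
    subset: Optional[Sequence[int]] = None,
    rarefaction_g: Optional[int] = None,
    null_method: str = "brookfield1",
) -> pd.DataFrame:
    """Per-locus summary: n, A, A_R, allele size range, H_O, H_E, null freq.

    ``rarefaction_g`` defaults to the smallest per-locus gene-copy count so
    richness is comparable across loci.
    """
    rows = []
    counts_per_locus = {}
    for locus in g.loci:
        pairs = _locus_calls(g, locus, subset)
        if pairs.shape[0] == 0:
            rows.append({"locus": locus, "n": 0})
            continue
        _, counts = np.unique(pairs.ravel(), return_counts=True)
        counts_per_locus[locus] = counts
    g_ref = rarefaction_g or min(
        (int(c.sum()) for c in counts_per_locus.values()), default=None
    )
    rows = []
    for locus in g.loci:
        pairs = _locus_calls(g, locus, subset)
        n = pairs.shape[0]
        if n < 2:
            rows.append({"locus": locus, "n": n})
            continue
        alleles = np.unique(pairs.ravel())
        h_o, h_e = heterozygosities(g, locus, subset)
        null = null_allele_frequency(h_e, h_o, null_method)
        rows.append(
            {
                "locus": locus,
                "n": n,
                "A": int(alleles.size),
                "A_R": allelic_richness_rarefied(counts_per_locus[locus], g_ref),
                "size_min": int(alleles.min()),
                "size_max": int(alleles.max()),
                "H_O": h_o,
                "H_E": h_e,
                "null_freq": null.frequency,
                "null_flag": null.flag,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["rarefaction_g"] = g_ref
    return df
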