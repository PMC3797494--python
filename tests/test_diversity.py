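from itertools import combinations

import numpy as np
import pytest

import sgskit as sk
from sgskit.diversity import NullAlleleEstimate

from conftest import make_dataset, random_hwe_dataset


class TestAlleleFrequencies:
    def test_basic_counts(self):
        g = make_dataset([[[1, 1]], [[1, 2]]])
        freqs = sk.allele_frequencies(g, "L0")
        assert freqs[1] == pytest.approx(0.75)
        assert freqs[2] == pytest.approx(0.25)
        assert freqs.attrs["n"] == 2

    def test_missing_excluded(self):
        g = make_dataset([[[1, 1]], [[0, 0]]])
        freqs = sk.allele_frequencies(g, "L0")
        assert freqs[1] == pytest.approx(1.0)
        assert freqs.attrs["n"] == 1

    def test_all_missing_raises(self):
        g = make_dataset([[[0, 0]], [[0, 0]]])
        with pytest.raises(ValueError, match="no non-missing"):
            sk.allele_frequencies(g, "L0")

    def test_sum_to_one(self, rng):
        g = random_hwe_dataset(rng, 30, [[0.2, 0.3, 0.5]])
        assert sk.allele_frequencies(g, "L0").sum() == pytest.approx(1.0, abs=1e-12)


class TestHeterozygosities:
    def test_all_heterozygous(self):
        g = make_dataset([[[1, 2]]] * 5)
        h_o, _ = sk.heterozygosities(g, "L0")
        assert h_o == 1.0

    def test_unbiased_expected_het(self):
        # AA x2, BB x2: H_E = (2n/(2n-1)) * (1 - 0.5) = 8/7 * 0.5
        g = make_dataset([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]])
        h_o, h_e = sk.heterozygosities(g, "L0")
        assert h_o == 0.0
        assert h_e == pytest.approx(4 / 7, abs=1e-12)

    def test_monomorphic(self):
        g = make_dataset([[[1, 1]]] * 4)
        assert sk.heterozygosities(g, "L0") == (0.0, 0.0)

    def test_relabeling_invariance(self, rng):
        g = random_hwe_dataset(rng, 25, [[0.4, 0.4, 0.2]])
        relabeled = make_dataset(g.calls * 7 + 3)
        assert sk.heterozygosities(g, "L0")[1] == pytest.approx(
            sk.heterozygosities(relabeled, "L0")[1]
        )


def enumerate_rarefied_richness(counts, g):
    """Exhaustive oracle: mean #distinct alleles over all g-subsets."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    subs = list(combinations(range(len(pool)), g))
    return np.mean([len({pool[i] for i in sub}) for sub in subs])


class TestRarefaction:
    def test_two_by_two_counts(self):
        # enumerate C(4,2)=6 subsamples: 2*(1 - 1/6)
        assert sk.allelic_richness_rarefied([2, 2], 2) == pytest.approx(5 / 3)

    def test_g_one_is_one(self):
        assert sk.allelic_richness_rarefied([5, 3, 1], 1) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert sk.allelic_richness_rarefied([9], 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [[2, 2], [3, 1], [4, 2, 2], [1, 1, 1, 5]])
    def test_matches_exhaustive_enumeration(self, counts):
        N = sum(counts)
        for g in range(1, N + 1):
            assert sk.allelic_richness_rarefied(counts, g) == pytest.approx(
                enumerate_rarefied_richness(counts, g), abs=1e-12
            )

    def test_monotone_and_full_sample(self):
        counts = [5, 3, 2, 1]
        values = [sk.allelic_richness_rarefied(counts, g) for g in range(1, 12)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(len(counts))

    def test_g_above_total_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            sk.allelic_richness_rarefied([2, 2], 5)


def wc_oracle(pop_genotypes):
    """Plain-loop Weir & Cockerham (1984) variance components.

    ``pop_genotypes``: list of populations, each a list of (a, b) calls.
    Returns summed (a, b, c) over alleles; independent of the package path.
    """
    r = len(pop_genotypes)
    ns = [len(p) for p in pop_genotypes]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n**2 for n in ns) / (r * nbar)) / (r - 1) if r > 1 else None
    alleles = sorted({a for p in pop_genotypes for pair in p for a in pair})
    A = B = C = 0.0
    for al in alleles:
        p_i, h_i = [], []
        for pop in pop_genotypes:
            p_i.append(sum(pair.count(al) for pair in pop) / (2 * len(pop)))
            h_i.append(sum(1 for pair in pop if pair.count(al) == 1) / len(pop))
        pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
        hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
        if r > 1:
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        A, B, C = A + a, B + b, C + hbar / 2
    return A, B, C


class TestWCFStatistics:
    def test_fixed_differences_theta_one(self):
        calls = np.array([[[1, 1]]] * 10 + [[[2, 2]]] * 10)
        g = make_dataset(calls, pops=["p1"] * 10 + ["p2"] * 10)
        assert sk.wc_f_statistics(g).theta == pytest.approx(1.0)

    def test_identical_hwe_pops_theta_near_zero(self):
        block = [[[1, 1]]] * 4 + [[[1, 2]]] * 8 + [[[2, 2]]] * 4
        g = make_dataset(np.array(block * 2), pops=["p1"] * 16 + ["p2"] * 16)
        res = sk.wc_f_statistics(g)
        assert abs(res.theta) < 0.05
        pops = [[tuple(c) for c in g.calls[:16, 0]], [tuple(c) for c in g.calls[16:, 0]]]
        A, B, C = wc_oracle(pops)
        assert res.theta == pytest.approx(A / (A + B + C), abs=1e-12)

    def test_single_pop_hwe_f_near_zero(self):
        calls = np.array([[[1, 1]]] * 25 + [[[1, 2]]] * 50 + [[[2, 2]]] * 25)
        g = make_dataset(calls)
        res = sk.wc_f_statistics(g)
        assert abs(res.f) < 0.05
        A, B, C = wc_oracle([[tuple(c) for c in calls[:, 0]]])
        assert res.f == pytest.approx(1 - C / (B + C), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(1, 4, size=(24, 2, 2))
        labels = ["p1"] * 12 + ["p2"] * 12
        g = make_dataset(calls, pops=labels)
        res = sk.wc_f_statistics(g)
        A = B = C = 0.0
        for j in range(2):
            pops = [
                [tuple(c) for c in g.calls[:12, j]],
                [tuple(c) for c in g.calls[12:, j]],
            ]
            a, b, c = wc_oracle(pops)
            A, B, C = A + a, B + b, C + c
        assert res.theta == pytest.approx(A / (A + B + C), abs=1e-12)
        assert res.f == pytest.approx(1 - C / (B + C), abs=1e-12)

    def test_multilocus_is_ratio_of_sums_not_mean_of_ratios(self, rng):
        g = make_dataset(
            rng.integers(1, 5, size=(30, 4, 2)), pops=["p1"] * 15 + ["p2"] * 15
        )
        res = sk.wc_f_statistics(g)
        per_locus_mean = res.per_locus["theta"].mean()
        tab = res.per_locus
        ratio_of_sums = tab["a"].sum() / (tab["a"] + tab["b"] + tab["c"]).sum()
        assert res.theta == pytest.approx(ratio_of_sums, abs=1e-12)
        assert res.theta != pytest.approx(per_locus_mean, abs=1e-9)

    def test_jackknife_se_present_with_multiple_loci(self, rng):
        g = make_dataset(
            rng.integers(1, 5, size=(30, 5, 2)), pops=["p1"] * 15 + ["p2"] * 15
        )
        res = sk.wc_f_statistics(g)
        assert res.jackknife_se["theta"] > 0


class TestFisInference:
    def test_all_homozygotes_maximal_inbreeding(self):
        calls = np.array(([[[1, 1]]] * 10 + [[[2, 2]]] * 10))
        g = make_dataset(calls)
        fis, p = sk.fis_inference(g, n_perm=1000, seed=7)
        assert fis == pytest.approx(1.0)
        assert p <= 0.01

    def test_fixed_seed_reproducible(self, rng):
        g = random_hwe_dataset(rng, 30, [[0.5, 0.5], [0.3, 0.7]])
        r1 = sk.fis_inference(g, n_perm=200, seed=42)
        r2 = sk.fis_inference(g, n_perm=200, seed=42)
        assert r1 == r2

    def test_monomorphic_undefined(self):
        g = make_dataset([[[1, 1]]] * 10)
        fis, p = sk.fis_inference(g, n_perm=100, seed=0)
        assert np.isnan(fis) and np.isnan(p)

    def test_small_n_perm_rejected(self, rng):
        g = random_hwe_dataset(rng, 10, [[0.5, 0.5]])
        with pytest.raises(ValueError, match="n_perm"):
            sk.fis_inference(g, n_perm=50)


class TestNullAlleles:
    def test_brookfield_formula(self):
        est = sk.null_allele_frequency(0.5, 0.4, "brookfield1")
        assert est.frequency == pytest.approx(0.1 / 1.5, abs=1e-4)
        assert est.flag == ""

    def test_chakraborty_formula(self):
        est = sk.null_allele_frequency(0.5, 0.4, "chakraborty")
        assert est.frequency == pytest.approx(0.1 / 0.9)

    def test_no_deficit_flagged(self):
        est = sk.null_allele_frequency(0.5, 0.5)
        assert est.frequency == 0.0
        assert est.flag == "no evidence"

    def test_undefined_when_no_variation(self):
        assert np.isnan(sk.null_allele_frequency(0.0, 0.0).frequency)

    def test_recovers_simulated_null_rate(self):
        """Median Brookfield estimate tracks the simulated null rate."""
        rate = 0.15
        estimates = []
        for seed in range(10):
            params = sk.IBDSimParams(
                habitat_side=300.0, census_density_D=20.0, sigma_seed=150.0,
                sigma_pollen=150.0, n_loci=6, n_generations=30, sample_size=80,
                null_allele_rate=rate, rng_seed=seed,
            )
            with pytest.warns(UserWarning):  # panmictic-dispersal warning
                g, _, _ = sk.simulate_ibd_population(params)
            for locus in g.loci:
                h_o, h_e = sk.heterozygosities(g, locus)
                estimates.append(sk.null_allele_frequency(h_e, h_o).frequency)
        assert abs(np.median(estimates) - rate) < 0.05


class TestModifiedFis:
    def test_empty_flag_list_matches_plain_estimate(self, rng):
        g = random_hwe_dataset(rng, 40, [[0.5, 0.5], [0.3, 0.7], [0.2, 0.8]])
        fis_plain, _ = sk.fis_inference(g, n_perm=100, seed=0)
        fis_mod, se, _ = sk.multilocus_fis_excluding_null(g, [])
        assert fis_mod == pytest.approx(fis_plain, abs=1e-12)
        assert se > 0

    def test_too_few_remaining_loci(self, rng):
        g = random_hwe_dataset(rng, 20, [[0.5, 0.5], [0.3, 0.7]])
        with pytest.raises(ValueError, match=">= 2 loci"):
            sk.multilocus_fis_excluding_null(g, ["L0"])

    def test_excluding_null_loci_moves_fis_toward_zero(self):
        """Corrupt half the loci with nulls; the modified F_IS should drop."""
        deltas = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 60
            clean = np.empty((n, 6, 2), dtype=np.int64)
            for j in range(6):
                clean[:, j] = rng.choice([1, 2, 3, 4], size=(n, 2))
            reads = clean.copy()
            null = rng.random((n, 3, 2)) < 0.25  # nulls on loci 0-2 only
            amp = np.where(null[..., 0], reads[:, :3, 1], reads[:, :3, 0])
            one = null[..., 0] ^ null[..., 1]
            reads[:, :3, 0] = np.where(one, amp, reads[:, :3, 0])
            reads[:, :3, 1] = np.where(one, amp, reads[:, :3, 1])
            reads[:, :3][null.all(axis=2)] = 0
            g = make_dataset(reads)
            full = sk.wc_f_statistics(g).f
            modified, _, _ = sk.multilocus_fis_excluding_null(g, ["L0", "L1", "L2"])
            deltas.append(abs(full) - abs(modified))
        assert np.median(deltas) > 0


def test_locus_summary_table_columns(rng):
    g = random_hwe_dataset(rng, 30, [[0.5, 0.5], [0.2, 0.3, 0.5]])
    tab = sk.locus_summary_table(g)
    assert set(tab.columns) >= {"locus", "n", "A", "A_R", "H_O", "H_E", "null_freq"}
    assert (tab["A_R"] <= tab["A"]).all()
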