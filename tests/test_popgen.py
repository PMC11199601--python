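"""Diversity statistics, covariance PCA, F_ST, and divergence estimates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ploidsv import popgen
from ploidsv.popgen import (
    FoldedAFS,
    f81_distance,
    folded_afs,
    haversine_km,
    hudson_fst,
    insertion_time,
    isolation_by_distance,
    mantel_test,
    neutral_folded_expectation,
    nucleotide_diversity,
    pca,
    ploidy_covariance,
    tajimas_d,
)


def oracle_tajima(n, eta):
    """Direct-formula Tajima's D, written independently (scalar arithmetic)."""
    S = sum(eta)
    if S < 3:
        return None
    pi = 0.0
    for j, count in enumerate(eta, start=1):
        pi += count * 2.0 * j * (n - j) / (n * (n - 1.0))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return None
    return (pi - S / a1) / var**0.5


class TestFoldedAfs:
    def test_single_carrier_diploids(self):
        d = np.array([[1.0, 0.0, 0.0]])
        afs = folded_afs(d, np.zeros((1, 3), bool), np.full(3, 2))
        assert afs.n_chrom == 6
        assert afs.counts[0] == 1 and afs.counts[1:].sum() == 0

    def test_half_count_folds_once(self):
        d = np.array([[2.0, 1.0, 0.0]])  # count 3 of n=6
        afs = folded_afs(d, np.zeros((1, 3), bool), np.full(3, 2))
        assert afs.counts[2] == 1 and afs.segregating_sites == 1

    def test_monomorphic_excluded(self):
        d = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 0.0]])
        afs = folded_afs(d, np.zeros((3, 2), bool), np.full(2, 2))
        assert afs.segregating_sites == 1

    def test_total_counts_conserved(self, small_cohort):
        rng = np.random.default_rng(0)
        truth = small_cohort["truth"]
        env = small_cohort["env"]
        samples = small_cohort["samples"]
        import ploidsv.synthcohort as sc

        g = sc.simulate_genotypes(truth.sv_freqs, samples, truth.populations,
                                  np.random.default_rng(1))
        x = np.array([s.ploidy for s in samples])
        cols = x == 2
        d = g[:, cols].astype(float)
        miss = np.zeros_like(d, dtype=bool)
        counts = d.sum(axis=1)
        n = int(x[cols].sum())
        poly = int(((counts > 0) & (counts < n)).sum())
        afs = folded_afs(d, miss, x[cols])
        assert afs.segregating_sites == poly
        # feature-class spectra partition the total spectrum
        feats = truth.sv["feature"].to_numpy()
        total = sum(
            folded_afs(d[feats == f], miss[feats == f], x[cols]).segregating_sites
            for f in ("exon", "intron", "flank", "intergenic")
        )
        assert total == afs.segregating_sites


class TestTajima:
    def test_toy_spectrum_matches_oracle(self):
        afs = FoldedAFS(10, np.array([3, 2, 1, 1, 1], dtype=float))
        res = tajimas_d(afs)
        assert res.D == pytest.approx(oracle_tajima(10, [3, 2, 1, 1, 1]), abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=4, max_value=12),
        data=st.data(),
    )
    def test_random_spectra_match_oracle(self, n, data):
        k = n // 2
        eta = data.draw(st.lists(st.integers(0, 30), min_size=k, max_size=k))
        res = tajimas_d(FoldedAFS(n, np.array(eta, dtype=float)))
        oracle = oracle_tajima(n, eta)
        if oracle is None:
            assert res.D is None
        else:
            assert res.D == pytest.approx(oracle, abs=1e-10)

    def test_neutral_spectrum_near_zero(self):
        n, S = 40, 5000
        afs = FoldedAFS(n, neutral_folded_expectation(n, S))
        assert abs(tajimas_d(afs).D) < 0.05

    def test_all_singletons_excluded_is_undefined(self):
        afs = FoldedAFS(10, np.array([12, 0, 0, 0, 0], dtype=float))
        res = tajimas_d(afs, exclude_singletons=True)
        assert res.D is None and "segregating" in res.reason

    def test_singleton_exclusion_raises_d(self):
        # removing the rare class must shift D upward for a rare-heavy AFS
        afs = FoldedAFS(10, np.array([40, 5, 3, 2, 2], dtype=float))
        assert tajimas_d(afs, True).D > tajimas_d(afs, False).D


class TestPi:
    def test_monomorphic_zero(self):
        assert nucleotide_diversity(np.array([]), 4, 100) == 0.0

    def test_single_site_value(self):
        # p = 0.5, n = 4 -> 2 * 0.25 * 4/3 = 2/3
        assert nucleotide_diversity(np.array([0.5]), 4, 1) == pytest.approx(2 / 3)

    def test_denominator_scales(self):
        one = nucleotide_diversity(np.array([0.5]), 4, 10)
        two = nucleotide_diversity(np.array([0.5]), 4, 20)
        assert one == pytest.approx(2 * two)


def oracle_diploid_covariance(geno, freqs):
    """Patterson-style diploid covariance via explicit loops."""
    n_ind = geno.shape[1]
    C = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(n_ind):
            total, m = 0.0, 0
            for s in range(geno.shape[0]):
                p = freqs[s]
                if p <= 0 or p >= 1:
                    continue
                total += (geno[s, i] / 2 - p) * (geno[s, j] / 2 - p) / (p * (1 - p))
                m += 1
            C[i, j] = total / m
    return C


class TestPloidyCovariance:
    def test_reduces_to_diploid_form(self):
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 3, size=(60, 8)).astype(float)
        x = np.full(8, 2)
        miss = np.zeros_like(geno, dtype=bool)
        C = ploidy_covariance(geno, miss, x)
        freqs = geno.sum(axis=1) / 16.0
        oracle = oracle_diploid_covariance(geno, freqs)
        assert np.allclose(C, oracle, atol=1e-12)

    def test_site_at_frequency_contributes_zero(self):
        # one individual with g/x == p contributes nothing on that site
        d = np.array([[1.0, 1.0, 2.0, 0.0]])  # p = 0.5 over 4 diploids
        x = np.full(4, 2)
        with pytest.raises(ValueError):
            # single site, but add a segregating second site to avoid m=0
            ploidy_covariance(d[[0, 0]][:0], np.zeros((0, 4), bool), x)
        C = ploidy_covariance(d, np.zeros((1, 4), bool), x)
        assert C[0, 0] == 0.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 5, size=(40, 6)).astype(float)
        x = np.array([2, 2, 4, 4, 2, 4])
        d = np.minimum(d, x[None, :])
        miss = np.zeros_like(d, dtype=bool)
        C = ploidy_covariance(d, miss, x)
        perm = np.array([3, 1, 0, 5, 2, 4])
        Cp = ploidy_covariance(d[:, perm], miss[:, perm], x[perm])
        assert np.allclose(Cp, C[np.ix_(perm, perm)], atol=1e-12)


class TestPca:
    def test_identity_equal_proportions(self):
        _, expl = pca(np.eye(5))
        assert np.allclose(expl, 0.2)

    def test_rank_one_explains_all(self):
        v = np.array([1.0, 2.0, 3.0])
        _, expl = pca(np.outer(v, v))
        assert expl[0] == pytest.approx(1.0)

    def test_eigen_reconstruction(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 6))
        C = A @ A.T
        vecs, expl = pca(C)
        vals = expl * np.trace(C)
        assert np.allclose(vecs @ np.diag(vals) @ vecs.T, C, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pca(np.array([[1.0, np.nan], [np.nan, 1.0]]))


class TestHudsonFst:
    def test_identical_large_samples_near_zero(self):
        p = np.array([0.3, 0.5, 0.7])
        res = hudson_fst(p, p, 1000, 1000)
        assert abs(res.fst) < 0.01

    def test_fixed_difference_is_one(self):
        res = hudson_fst(np.array([0.0]), np.array([1.0]), 20, 20)
        assert res.fst == pytest.approx(1.0)

    def test_two_site_ratio_of_averages(self):
        p1, p2 = np.array([0.2, 0.9]), np.array([0.6, 0.1])
        n1 = n2 = np.array([10.0, 10.0])
        num = sum(
            (a - b) ** 2 - a * (1 - a) / 9 - b * (1 - b) / 9
            for a, b in zip(p1, p2)
        )
        den = sum(a * (1 - b) + b * (1 - a) for a, b in zip(p1, p2))
        assert hudson_fst(p1, p2, n1, n2).fst == pytest.approx(num / den, abs=1e-12)

    def test_no_variation_undefined(self):
        res = hudson_fst(np.array([0.0]), np.array([0.0]), 10, 10)
        assert res.fst is None


class TestGeography:
    def test_coincident_points_zero(self):
        assert haversine_km(5.0, 50.0, 5.0, 50.0) == 0.0

    def test_antipodal_half_circumference(self):
        d = haversine_km(0.0, 0.0, 180.0, 0.0)
        assert d == pytest.approx(np.pi * 6371.0088, rel=1e-6)  # ~20015 km

    def test_mantel_perfect_correlation(self):
        lon = np.array([0.0, 1.0, 2.0, 3.0])
        lat = np.full(4, 50.0)
        D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        r, p = mantel_test(D, 2.5 * D, permutations=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.2  # small n limits attainable p

    def test_isolation_by_distance_table(self):
        fst = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        pairs, r, p = isolation_by_distance(
            fst, ["a", "b", "c"], {"a": 2, "b": 2, "c": 4},
            np.array([0.0, 1.0, 2.0]), np.array([50.0, 50.0, 50.0]),
            permutations=99, seed=1,
        )
        assert len(pairs) == 3
        assert set(pairs["pair_class"]) == {"diploid", "between"}


class TestF81:
    def test_identical_sequences_zero(self):
        assert f81_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_equal_base_frequency_closed_form(self):
        # B = 0.75, p = 0.1 -> K = -0.75 ln(1 - 0.1/0.75) ~ 0.10732
        n = 10_000
        quarter = "ACGT" * (n // 4)
        seq1 = quarter
        # mutate exactly 10% of sites cyclically (A->C, C->G, ...), keeping
        # the pooled composition uniform
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # mutate every 10th codon-like block so exactly 10% of EACH base
        # rotates, keeping the pooled composition exactly uniform
        seq2 = "".join(
            rot[c] if (i // 4) % 10 == 0 else c for i, c in enumerate(seq1)
        )
        K = f81_distance(seq1, seq2)
        assert K == pytest.approx(-0.75 * np.log(1 - 0.1 / 0.75), abs=1e-6)

    def test_correction_inflates(self):
        rng = np.random.default_rng(11)
        import ploidsv.synthcohort as sc

        a, b = sc.simulate_divergent_pair(20_000, T=2e6, seed=12)
        p = np.mean([x != y for x, y in zip(a, b)])
        assert f81_distance(a, b) >= p

    def test_gaps_excluded_pairwise(self):
        assert f81_distance("ACGT-ACGT", "ACGTTACGT") == 0.0

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturation"):
            f81_distance("AAAACCCCGGGGTTTT", "CCCCGGGGTTTTAAAA")


class TestInsertionTime:
    def test_zero_divergence(self):
        assert insertion_time(0.0).T == 0.0

    def test_million_year_arithmetic(self):
        est = insertion_time(1.39e-2, 6.95e-9)
        assert est.T == pytest.approx(1_000_000)

    def test_rate_scaling(self):
        assert insertion_time(0.01, 2e-8).T == pytest.approx(
            insertion_time(0.01, 1e-8).T / 2
        )

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            insertion_time(0.01, 0.0)
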