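import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chukarpop.io_formats import GenotypeMatrix, SequenceAlignment
from chukarpop.popgen_stats import (
    SaturationError,
    collapse_and_diversity,
    ewens_log_pmf,
    fus_fs,
    k2p_distance,
    k2p_matrix,
    msat_summaries,
    pairwise_differences,
    phist_matrix,
    tajimas_d,
    wc_fst,
)


def _aln(seqs, pops=None):
    pops = pops or ["p1"] * len(seqs)
    return SequenceAlignment([f"s{i}" for i in range(len(seqs))], seqs, pops)


class TestDiversity:
    def test_identical_pair(self):
        d = collapse_and_diversity(_aln(["ACGT", "ACGT"]))
        assert d.k == 1 and d.h == 0 and d.d == 0

    def test_three_site_difference(self):
        d = collapse_and_diversity(_aln(["AAAAAA", "AATTTA"]))
        assert d.d == 3 and d.s == 3 and d.h == 1

    def test_unbiased_h_on_2_1_1_frequencies(self, toy_alignment):
        # h = (4/3)(1 - (1/4 + 1/16 + 1/16)) = 0.8333...
        d = collapse_and_diversity(toy_alignment)
        assert d.k == 3 and d.K == 3
        assert d.h == pytest.approx(5 / 6, abs=1e-9)

    def test_gap_columns_excluded_from_k_only(self):
        d = collapse_and_diversity(_aln(["AC-T", "ACAT", "ACTT"]))
        assert d.K == 3
        assert d.k == 1  # gap column removed; remaining ACT identical

    def test_pairwise_deletion_of_n_sites(self):
        D = pairwise_differences(_aln(["ANGT", "ATGT"]))
        assert D[0, 1] == 0  # the only mismatch is against an N


class TestK2P:
    def test_identical(self):
        assert k2p_distance("A" * 100, "A" * 100) == 0

    def test_single_transition_closed_form(self):
        s1 = "A" * 100
        s2 = "G" + "A" * 99
        # -(1/2)ln(1-2*0.01) = 0.0101015...
        assert k2p_distance(s1, s2) == pytest.approx(0.0101015, abs=1e-6)

    def test_single_transversion_closed_form(self):
        s1 = "A" * 100
        s2 = "C" + "A" * 99
        # -(1/2)ln(1-0.01) - (1/4)ln(1-0.02) = 0.0100759...
        assert k2p_distance(s1, s2) == pytest.approx(0.0100759, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AG" * 50, "GA" * 50)

    @given(st.integers(0, 20), st.integers(0, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_correction_at_least_p_distance(self, n_ts, n_tv):
        L = 200
        seq = ["A"] * L
        other = list(seq)
        for i in range(n_ts):
            other[i] = "G"
        for i in range(n_ts, n_ts + n_tv):
            other[i] = "C"
        p_dist = (n_ts + n_tv) / L
        d = k2p_distance("".join(seq), "".join(other))
        assert d >= p_dist - 1e-12


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        """n=4 with 8 singleton + 3 doubleton sites: mean pairwise
        difference = 6 = s/a1 exactly, so the numerator vanishes."""
        L = 11
        seqs = [["A"] * L for _ in range(4)]
        owners = [0, 0, 1, 1, 2, 2, 3, 3]  # singleton sites 0..7
        for site, owner in enumerate(owners):
            seqs[owner][site] = "T"
        for site in (8, 9, 10):             # doubletons shared by 0 and 1
            seqs[0][site] = "T"
            seqs[1][site] = "T"
        aln = _aln(["".join(s) for s in seqs])
        assert tajimas_d(aln) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(_aln(["ACGT", "ACGT"])))

    def test_neutral_simulations_center_on_zero(self):
        from chukarpop.coalescent import simulate_mtdna

        vals = []
        for seed in range(300):
            aln = simulate_mtdna(20, theta=5.0, L=2000, seed=seed)
            d = tajimas_d(aln)
            if not math.isnan(d):
                vals.append(d)
        # constant-size neutral expectation ~ 0 (slightly negative skew)
        assert abs(np.mean(vals)) < 0.15


class TestFusFs:
    def test_ewens_three_sample_example(self):
        # n=3, theta=1: P(K=3) = 1/6 -> Fs = ln(1/5)
        seqs = ["AAAA", "AATA", "TTAA"]
        aln = _aln(seqs)
        # mean pairwise differences: (1 + 3 + 2)/3 = 2 -> use explicit theta
        logp = ewens_log_pmf(3, 1.0)
        assert np.exp(logp[3]) == pytest.approx(1 / 6, abs=1e-12)

    def test_monomorphic_sample_is_undefined(self):
        # d = 0 -> undefined
        assert math.isnan(fus_fs(_aln(["AAAA", "AAAA", "AAAA"])))

    def test_excess_haplotypes_give_negative_fs(self):
        # many distinct haplotypes at low diversity
        seqs = ["AAAAAAAA", "AAAAAAAT", "AAAAAATA", "AAAAATAA", "AAAATAAA"]
        assert fus_fs(_aln(seqs)) < 0

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_bruteforce_ewens_enumeration(self, n):
        """|S(n,k)| from expanding theta(theta+1)...(theta+n-1)."""
        theta = 1.7
        poly = np.array([1.0])
        for i in range(n):
            # multiply by (theta + i): coefficients in ascending powers
            poly = np.append(poly * i, 0.0) + np.append(0.0, poly)
        rising = 1.0
        for i in range(n):
            rising *= theta + i
        brute = np.array([poly[k] * theta**k for k in range(n + 1)]) / rising
        mine = np.exp(ewens_log_pmf(n, theta))
        np.testing.assert_allclose(mine, brute, rtol=1e-10)


class TestPhiST:
    def test_identical_composition_near_zero(self):
        # identical haplotype compositions: estimate ~ 0, with the
        # estimator's small negative finite-sample bias (-1/(n-1)-like),
        # never truncated
        seqs = (["AAAA"] * 10 + ["AATT"] * 10) * 2
        pops = ["p1"] * 20 + ["p2"] * 20
        aln = _aln(seqs, pops)
        m, _ = phist_matrix(aln, distance="diff")
        assert -0.06 <= m.loc["p1", "p2"] <= 0.001

    def test_fixed_difference_gives_one(self, two_pop_alignment):
        m, _ = phist_matrix(two_pop_alignment, distance="diff")
        assert m.loc["p1", "p2"] == pytest.approx(1.0)

    def test_matches_bruteforce_amova(self):
        """3+3 toy with one shared and one private haplotype, checked
        against variance components computed from explicit sums."""
        seqs = ["AAAA", "AAAA", "AATT", "AAAA", "CCAA", "CCAA"]
        pops = ["p1"] * 3 + ["p2"] * 3
        aln = _aln(seqs, pops)
        m, _ = phist_matrix(aln, distance="diff")

        D2 = pairwise_differences(aln) ** 2
        N, P = 6, 2
        ss_total = sum(D2[i, j] for i, j in itertools.combinations(range(N), 2)) / N
        ss_within = (
            sum(D2[i, j] for i, j in itertools.combinations(range(3), 2)) / 3
            + sum(D2[i, j] for i, j in itertools.combinations(range(3, 6), 2)) / 3
        )
        sigma_w = ss_within / (N - P)
        n_prime = (N - (9 + 9) / N) / (P - 1)
        sigma_a = ((ss_total - ss_within) / (P - 1) - sigma_w) / n_prime
        expected = sigma_a / (sigma_a + sigma_w)
        assert m.loc["p1", "p2"] == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_population_order(self, two_pop_alignment):
        m1, _ = phist_matrix(two_pop_alignment, distance="diff")
        rev = two_pop_alignment.subset([3, 4, 5, 0, 1, 2])
        m2, _ = phist_matrix(rev, distance="diff")
        assert m1.loc["p1", "p2"] == pytest.approx(m2.loc["p2", "p1"])

    def test_permutation_pvalue_small_for_fixed_difference(self, two_pop_alignment):
        _, p = phist_matrix(
            two_pop_alignment, distance="diff", n_permutations=99, seed=1
        )
        assert p.loc["p1", "p2"] <= 0.15


class TestMicrosats:
    def test_fixed_population_has_undefined_fis(self):
        alleles = np.full((3, 2, 2), 120)
        G = GenotypeMatrix(["a", "b", "c"], ["l1", "l2"], alleles, ["p"] * 3)
        t = msat_summaries(G)
        assert t.loc["p", "He"] == 0 and t.loc["p", "Ho"] == 0
        assert math.isnan(t.loc["p", "FIS"])

    def test_hand_computed_het_and_fis(self):
        # one locus, two individuals both 120/140:
        # Ho = 1, He = (4/3)(1 - 0.5) = 2/3, FIS = 1 - 1/(2/3) = -0.5
        alleles = np.array([[[120, 140]], [[120, 140]]])
        G = GenotypeMatrix(["a", "b"], ["l1"], alleles, ["p", "p"])
        t = msat_summaries(G)
        assert t.loc["p", "Ho"] == pytest.approx(1.0)
        assert t.loc["p", "He"] == pytest.approx(2 / 3)
        assert t.loc["p", "FIS"] == pytest.approx(-0.5)

    def test_monomorphic_locus_leaves_other_loci_alone(self):
        a1 = np.array([[[120, 140]], [[120, 120]]])
        G1 = GenotypeMatrix(["a", "b"], ["l1"], a1, ["p", "p"])
        a2 = np.concatenate([a1, np.full((2, 1, 2), 200)], axis=1)
        G2 = GenotypeMatrix(["a", "b"], ["l1", "l2"], a2, ["p", "p"])
        t1, t2 = msat_summaries(G1), msat_summaries(G2)
        # per-locus values of l1 unchanged; means now include l2
        assert t2.loc["p", "Ho"] == pytest.approx(t1.loc["p", "Ho"] / 2)

    def test_wc_theta_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        base = rng.choice([120, 122, 124], size=(40, 1, 2))
        G = GenotypeMatrix(
            [f"i{k}" for k in range(40)], ["l1"], base, ["p1"] * 20 + ["p2"] * 20
        )
        theta = wc_fst(G).loc["p1", "p2"]
        assert abs(theta) < 0.08

    def test_wc_theta_fixed_difference_is_one(self):
        alleles = np.concatenate(
            [np.full((10, 1, 2), 120), np.full((10, 1, 2), 140)]
        )
        G = GenotypeMatrix(
            [f"i{k}" for k in range(20)], ["l1"], alleles, ["p1"] * 10 + ["p2"] * 10
        )
        assert wc_fst(G).loc["p1", "p2"] == pytest.approx(1.0)

    def test_wc_theta_matches_independent_variance_components(self):
        """One locus, two alleles, 10+10: direct a/(a+b+c) evaluation."""
        rng = np.random.default_rng(3)
        alleles = np.where(rng.random((20, 1, 2)) < 0.3, 120, 140)
        alleles[10:] = np.where(rng.random((10, 1, 2)) < 0.7, 120, 140)
        alleles.sort(axis=2)
        G = GenotypeMatrix(
            [f"i{k}" for k in range(20)], ["l1"], alleles, ["p1"] * 10 + ["p2"] * 10
        )
        theta = wc_fst(G).loc["p1", "p2"]

        def components(allele):
            r, n1, n2 = 2, 10, 10
            nbar = 10.0
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            p1 = (alleles[:10] == allele).mean()
            p2 = (alleles[10:] == allele).mean()
            h1 = ((alleles[:10, 0, 0] == allele) ^ (alleles[:10, 0, 1] == allele)).mean()
            h2 = ((alleles[10:, 0, 0] == allele) ^ (alleles[10:, 0, 1] == allele)).mean()
            pbar = (p1 + p2) / 2
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (h1 + h2) / 2
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            return a, b, hbar / 2

        A = B = C = 0.0
        for al in (120, 140):
            a, b, c = components(al)
            A, B, C = A + a, B + b, C + c
        assert theta == pytest.approx(A / (A + B + C), rel=1e-10)


class TestMatrixProperties:
    def test_k2p_matrix_symmetric_zero_diagonal(self, toy_alignment):
        D = k2p_matrix(toy_alignment)
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_relabeling_within_population_invariance(self, two_pop_alignment):
        m1, _ = phist_matrix(two_pop_alignment, distance="diff")
        swapped = two_pop_alignment.subset([1, 0, 2, 4, 3, 5])
        m2, _ = phist_matrix(swapped, distance="diff")
        assert m1.loc["p1", "p2"] == pytest.approx(m2.loc["p1", "p2"])
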