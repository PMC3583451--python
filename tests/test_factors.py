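"""LD r^2 (EM), LD classification, factor binning, distance, PEV, Fst."""

import itertools

import numpy as np
import pytest

import markerimpute as mi
from markerimpute import factors as fct

from conftest import toy_matrix

NA = np.nan


class TestLDr2:
    def test_identical_inbred_markers_give_one(self):
        a = np.array([-1.0, 1, 1, -1, 1, -1])
        assert fct.ld_r2_em(a, a) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # 2x2 haplotype counts exactly at independence: D = 0
        a = np.array([1.0, 1, -1, -1] * 2)
        b = np.array([1.0, -1, 1, -1] * 2)
        assert fct.ld_r2_em(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_and_order_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.choice([-1.0, 1.0], 30)
        b = rng.choice([-1.0, 1.0], 30)
        v = fct.ld_r2_em(a, b)
        assert fct.ld_r2_em(b, a) == pytest.approx(v)
        assert fct.ld_r2_em(-a, b) == pytest.approx(v)

    def test_em_equals_count_based_r2_on_complete_inbred_data(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.choice([-1.0, 1.0], 40)
            b = np.where(rng.random(40) < 0.3, -a, a)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            r2_count = np.corrcoef(a, b)[0, 1] ** 2
            assert fct.ld_r2_em(a, b) == pytest.approx(r2_count, abs=1e-10)

    def test_em_matches_grid_search_mle_with_double_heterozygotes(self):
        # 12 individuals incl. two double hets: EM x11 maximises the
        # random-union genotype likelihood; compare to an exhaustive grid
        a = np.array([1.0, 1, 0, 0, -1, -1, 1, 0, -1, 1, -1, 0])
        b = np.array([1.0, 0, 0, 1, -1, 0, 1, 0, -1, -1, 1, 1])
        da, db = a + 1, b + 1
        pA, pB = da.sum() / 24, db.sum() / 24

        def loglik(x11):
            f = np.array([x11, pA - x11, pB - x11, 1 - pA - pB + x11])
            if np.any(f < 0):
                return -np.inf
            ll = 0.0
            for ga, gb in zip(da, db):
                prob = 0.0
                for (h1a, h1b), (h2a, h2b) in itertools.product(
                    [(1, 1), (1, 0), (0, 1), (0, 0)], repeat=2
                ):
                    if h1a + h2a == ga and h1b + h2b == gb:
                        prob += (
                            f[fct._hap_index(h1a, h1b)] * f[fct._hap_index(h2a, h2b)]
                        )
                ll += np.log(max(prob, 1e-300))
            return ll

        lo, hi = max(0, pA + pB - 1), min(pA, pB)
        grid = np.linspace(lo, hi, 200_001)
        x11_best = grid[np.argmax([loglik(x) for x in grid[:: 1]])]
        D = x11_best - pA * pB
        r2_grid = D * D / (pA * (1 - pA) * pB * (1 - pB))
        assert fct.ld_r2_em(a, b) == pytest.approx(r2_grid, abs=1e-4)

    def test_monomorphic_marker_flagged_undefined(self):
        a = np.ones(10)
        b = np.array([1.0, -1] * 5)
        assert np.isnan(fct.ld_r2_em(a, b))


class TestLDClassify:
    def test_duplicated_pair_is_moderate(self):
        rng = np.random.default_rng(1)
        base = rng.choice([-1.0, 1.0], 30)
        other = rng.choice([-1.0, 1.0], 30)
        gm = toy_matrix(np.column_stack([base, base, other]))
        summary = fct.ld_classify(gm)
        assert summary.class_per_marker[0] == fct.LDClass.MODERATE_LD
        assert summary.class_per_marker[1] == fct.LDClass.MODERATE_LD

    def test_zero_threshold_marks_everything_moderate(self):
        rng = np.random.default_rng(2)
        gm = toy_matrix(rng.choice([-1.0, 1.0], (20, 4)))
        summary = fct.ld_classify(gm, threshold=0.0)
        assert all(c == fct.LDClass.MODERATE_LD for c in summary.class_per_marker)

    def test_independent_markers_are_low_ld_at_large_m(self):
        rng = np.random.default_rng(3)
        gm = toy_matrix(rng.choice([-1.0, 1.0], (600, 12)))
        summary = fct.ld_classify(gm)
        assert all(c == fct.LDClass.LOW_LD for c in summary.class_per_marker)


class TestLDRatio:
    def _summary(self, classes):
        return fct.LDSummary(
            max_r2_per_marker=np.where(
                np.array(classes) == fct.LDClass.MODERATE_LD, 0.9, 0.1
            ),
            class_per_marker=np.array(classes, dtype=object),
        )

    def test_equal_medians_give_one(self):
        s = self._summary([fct.LDClass.LOW_LD, fct.LDClass.MODERATE_LD])
        assert fct.ld_ratio(s, np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_reduced_ratio_arithmetic(self):
        # low-LD median 0.13 over moderate-LD median 0.8 -> 0.1625
        s = self._summary(
            [fct.LDClass.LOW_LD] * 2 + [fct.LDClass.MODERATE_LD] * 2
        )
        ratio = fct.ld_ratio(s, np.array([0.13, 0.13, 0.8, 0.8]))
        assert ratio == pytest.approx(0.1625)

    def test_empty_class_is_an_error(self):
        s = self._summary([fct.LDClass.MODERATE_LD] * 3)
        with pytest.raises(ValueError, match="empty"):
            fct.ld_ratio(s, np.array([0.1, 0.2, 0.3]))


class TestBinning:
    def test_maf_rounds_to_nearest_tenth(self):
        t = fct.bin_accuracy_by("MAF", [0.04, 0.06], [0.5, 0.7])
        assert list(t["bin"]) == [0.0, 0.1]

    def test_nonmissing_rounds_to_nearest_five(self):
        t = fct.bin_accuracy_by("N_NONMISSING", [12, 13, 18], [0.1, 0.3, 0.5])
        assert list(t["bin"]) == [10.0, 15.0, 20.0]

    def test_single_bin_median(self):
        t = fct.bin_accuracy_by("DISTANCE", [3.2, 2.8, 3.1], [0.2, 0.4, 0.9])
        assert len(t) == 1
        assert t["median_accuracy"].iloc[0] == pytest.approx(0.4)

    def test_monotone_construction_stays_monotone(self):
        counts = np.repeat([10, 20, 30, 40], 8)
        accs = counts / 50 + 0.01 * np.sin(np.arange(32))
        t = fct.bin_accuracy_by("N_NONMISSING", counts, accs)
        assert t["median_accuracy"].is_monotonic_increasing

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fct.bin_accuracy_by("MAF", [0.1], [0.5, 0.6])


class TestDistance:
    def test_duplicated_individual_has_zero_distance(self):
        vals = np.array([[1.0, -1, 1], [1, -1, 1], [-1, 1, -1]])
        d = fct.closest_relative_distance(toy_matrix(vals))
        assert d[0] == 0.0 and d[1] == 0.0

    def test_hand_distance(self):
        vals = np.array([[1.0, 1], [-1, 1]])
        d = fct.closest_relative_distance(toy_matrix(vals))
        np.testing.assert_allclose(d, [2.0, 2.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        vals = rng.choice([-1.0, 1.0], (5, 8))
        d = fct.closest_relative_distance(toy_matrix(vals))
        for i in range(5):
            brute = min(
                np.sqrt(((vals[i] - vals[k]) ** 2).sum())
                for k in range(5) if k != i
            )
            assert d[i] == pytest.approx(brute)

    def test_missing_cells_rejected(self):
        gm = toy_matrix([[1, NA], [1, 1]])
        with pytest.raises(ValueError, match="missing"):
            fct.closest_relative_distance(gm)


class TestPEV:
    def test_matches_direct_mme_inversion_on_toy(self):
        vals = np.array([[1.0, -1], [1, 1], [-1, 1], [-1, -1], [1, 1]])
        gm = toy_matrix(vals)
        sg, se = 0.8, 0.4
        got = fct.pev_per_individual(gm, variance_components=(sg, se))

        # oracle: assemble and invert the coefficient matrix per marker
        m = 5
        Z = vals - vals.mean(axis=0, keepdims=True)
        total = np.zeros(m)
        for j in range(2):
            z = Z[:, [1 - j]]
            K = (z @ z.T) / ((z**2).sum() / m)
            Kinv = np.linalg.inv(K + 1e-8 * np.eye(m))
            C = np.zeros((m + 1, m + 1))
            C[0, 0] = m / se
            C[0, 1:] = C[1:, 0] = 1 / se
            C[1:, 1:] = np.eye(m) / se + Kinv / sg
            total += np.diag(np.linalg.inv(C))[1:]
        np.testing.assert_allclose(got, total, rtol=1e-8)

    def test_duplicated_individual_has_lower_pev_than_isolated_one(self):
        rng = np.random.default_rng(33)
        base = rng.choice([-1.0, 1.0], (4, 30))
        vals = np.vstack([np.tile(base[0], (5, 1)), base[1:],
                          rng.choice([-1.0, 1.0], (1, 30))])
        gm = toy_matrix(vals)
        pev = fct.pev_per_individual(gm, variance_components=(1.0, 1.0))
        assert pev[:5].mean() < pev[-1]

    def test_vanishing_genetic_variance_returns_prior_variance(self):
        rng = np.random.default_rng(34)
        vals = rng.choice([-1.0, 1.0], (6, 10))
        gm = toy_matrix(vals)
        sg = 1e-8
        pev = fct.pev_per_individual(gm, variance_components=(sg, 1.0))
        # no information flows: PEV -> prior variance sigma2_g * K_ii
        Z = vals - vals.mean(axis=0, keepdims=True)
        G = Z @ Z.T
        css = (Z**2).sum(axis=0)
        prior = np.zeros(6)
        for j in range(10):
            Kj = (G - np.outer(Z[:, j], Z[:, j])) / ((np.trace(G) - css[j]) / 6)
            prior += sg * np.diag(Kj)
        np.testing.assert_allclose(pev, prior, rtol=1e-3)

    def test_invariant_to_marker_permutation(self):
        rng = np.random.default_rng(35)
        vals = rng.choice([-1.0, 1.0], (8, 12))
        gm = toy_matrix(vals)
        perm = rng.permutation(12)
        a = fct.pev_per_individual(gm, variance_components=(1.0, 0.5))
        b = fct.pev_per_individual(
            gm.select_markers(perm), variance_components=(1.0, 0.5)
        )
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestFst:
    def test_identical_group_frequencies_near_zero(self):
        block = np.tile([[1.0], [1], [-1], [-1]], (5, 1))  # p = 0.5, n = 20
        vals = np.vstack([block, block])
        gm = toy_matrix(vals)
        fst = fct.fst_per_marker(gm, ["a"] * 20 + ["b"] * 20)
        # unbiased estimator: at most a small negative bias term
        assert fst[0] < 0.05 and fst[0] > -0.15

    def test_fixed_differences_near_one(self):
        vals = np.vstack([np.ones((6, 1)), -np.ones((6, 1))])
        vals = np.hstack([vals, np.tile([[1.0], [-1]], (6, 1))])
        gm = toy_matrix(vals)
        fst = fct.fst_per_marker(gm, ["a"] * 6 + ["b"] * 6)
        assert fst[0] > 0.9

    def test_textbook_hand_calculation(self):
        # two groups of 4 haploid observations, p1 = 0.75, p2 = 0.25
        vals = np.array([[1.0], [1], [1], [-1], [1], [-1], [-1], [-1]])
        gm = toy_matrix(vals)
        fst = fct.fst_per_marker(gm, ["a"] * 4 + ["b"] * 4)
        ni = np.array([4.0, 4.0])
        pi = np.array([0.75, 0.25])
        ntot, r = 8.0, 2
        pbar = 0.5
        nc = (ntot - (ni**2).sum() / ntot) / (r - 1)
        msp = (ni * (pi - pbar) ** 2).sum() / (r - 1)
        msg = (ni * pi * (1 - pi)).sum() / (ntot - r)
        expect = (msp - msg) / (msp + (nc - 1) * msg)
        assert fst[0] == pytest.approx(expect)

    def test_group_validation(self):
        gm = toy_matrix([[1.0], [1], [-1]])
        with pytest.raises(ValueError):
            fct.fst_per_marker(gm, ["a", "a", "b"])
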