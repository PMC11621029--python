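import math

import numpy as np
import pytest
from scipy import stats as sps

from bflow import (
    bfa_permutation,
    bfl_scores,
    cohens_d_from_bfl,
    erf_pvalue,
    log_linear_dose_model,
    manhattan_group_distance,
    per_unit_tests,
    power_curve,
    sensitivity_assay,
    stratify_responders,
)
from bflow.flow import TransitionMatrix
from bflow.stats import GroupedTransitionSet, _by_adjust
from conftest import random_transition_matrices


def _mat(cells, rid=""):
    cells = np.asarray(cells, dtype=np.int64)
    return TransitionMatrix(counts=cells, alphabet=np.arange(len(cells)),
                            recording_id=rid)


class TestManhattanDistance:
    def test_hand_example(self):
        g = GroupedTransitionSet(group_C=[_mat([[0, 2], [3, 0]])],
                                 group_T=[_mat([[0, 4], [1, 0]])])
        assert manhattan_group_distance(g) == 4.0

    def test_identical_means_zero_and_symmetry(self, rng):
        mats = random_transition_matrices(rng, 4)
        g = GroupedTransitionSet(group_C=mats[:2], group_T=mats[:2])
        assert manhattan_group_distance(g) == 0.0
        a = GroupedTransitionSet(group_C=mats[:2], group_T=mats[2:])
        b = GroupedTransitionSet(group_C=mats[2:], group_T=mats[:2])
        assert manhattan_group_distance(a) == manhattan_group_distance(b)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(1000):
            mats = random_transition_matrices(rng, 5, nc=3)
            g = GroupedTransitionSet(group_C=mats[:2], group_T=mats[2:])
            got = manhattan_group_distance(g)
            exp = 0.0
            for j in range(3):
                for k in range(3):
                    mc = sum(m.counts[j, k] for m in mats[:2]) / 2
                    mt = sum(m.counts[j, k] for m in mats[2:]) / 3
                    exp += abs(mc - mt)
            assert got == pytest.approx(exp, rel=1e-12)


class TestErfPvalue:
    def test_zero_gives_half(self):
        assert erf_pvalue(0.0) == 0.5

    def test_printed_worked_values(self):
        # right-tailed P at the two-decimal z values reported for the
        # swim-stress (z = 3.09) and social-instability (z = 5.72) analyses
        assert erf_pvalue(3.09) == pytest.approx(1.01e-3, rel=0.02)
        assert erf_pvalue(5.72) == pytest.approx(5.3e-9, rel=0.02)

    def test_matches_normal_upper_tail_oracle(self):
        z = np.linspace(-8, 8, 1601)
        for zi in z:
            assert erf_pvalue(zi) == pytest.approx(sps.norm.sf(zi), rel=1e-12)


class TestBFA:
    def test_distance_at_null_mean_gives_z_zero(self, rng):
        # symmetric-null construction: both groups from one pool
        mats = random_transition_matrices(rng, 20, nc=4)
        g = GroupedTransitionSet(group_C=mats[:10], group_T=mats[10:])
        res = bfa_permutation(g, n_perm=500, seed=1)
        # directly check the formulas rather than a special input
        assert res.z == pytest.approx(
            (res.distance - res.null.distances.mean()) / res.null.distances.std())
        assert res.p == pytest.approx(erf_pvalue(res.z))

    def test_percentile_ceiling_with_disjoint_patterns(self):
        a = [_mat([[0, 9], [9, 0]], rid=f"a{i}") for i in range(15)]
        b = [_mat([[0, 0], [0, 0]], rid=f"b{i}") for i in range(15)]
        # zero matrices in one group give a degenerate null; offset slightly
        b = [_mat(np.array([[0, 1], [1, 0]]) * (i % 2), rid=f"b{i}")
             for i in range(15)]
        g = GroupedTransitionSet(group_C=a, group_T=b)
        res = bfa_permutation(g, n_perm=1000, seed=0)
        assert res.percentile == pytest.approx(100 * 1000 / 1001)
        assert round(res.percentile, 1) == 99.9

    def test_percentile_never_exceeds_ceiling(self, rng):
        mats = random_transition_matrices(rng, 12, nc=3)
        for seed in range(5):
            g = GroupedTransitionSet(group_C=mats[:6], group_T=mats[6:])
            res = bfa_permutation(g, n_perm=99, seed=seed)
            assert res.percentile <= 100 * 99 / 100

    def test_reproducible_given_seed(self, rng):
        mats = random_transition_matrices(rng, 10, nc=3)
        g = GroupedTransitionSet(group_C=mats[:5], group_T=mats[5:])
        r1 = bfa_permutation(g, n_perm=200, seed=7)
        r2 = bfa_permutation(g, n_perm=200, seed=7)
        np.testing.assert_array_equal(r1.null.distances, r2.null.distances)

    def test_permutations_preserve_group_sizes(self, rng):
        """The null of unbalanced groups uses the same group sizes."""
        mats = random_transition_matrices(rng, 12, nc=3)
        g = GroupedTransitionSet(group_C=mats[:4], group_T=mats[4:])
        res = bfa_permutation(g, n_perm=100, seed=3)
        # a size-preserving shuffle of identical matrices gives distance 0
        same = GroupedTransitionSet(group_C=[mats[0]] * 4, group_T=[mats[0]] * 8)
        with pytest.raises(ValueError, match="degenerate"):
            bfa_permutation(same, n_perm=50, seed=0)
        assert res.null.n == 100


class TestBenjaminiYekutieli:
    def test_matches_step_up_formula(self, rng):
        """BY adjustment vs the textbook step-up computation, 1,000 fixtures."""
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(0, 1, m)
            got = _by_adjust(p)
            c_m = np.sum(1.0 / np.arange(1, m + 1))
            order = np.argsort(p)
            adj = p[order] * c_m * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            adj = np.minimum(adj, 1.0)
            expected = np.empty(m)
            expected[order] = adj
            np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_adjusted_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = _by_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPerUnitTests:
    def test_identical_groups_give_p_one(self, rng):
        mats = random_transition_matrices(rng, 3, nc=3)
        g = GroupedTransitionSet(group_C=mats, group_T=mats)
        table = per_unit_tests(g)
        assert (table["p"] == 1.0).all()

    def test_injected_shift_has_smallest_adjusted_p(self, rng):
        n = 10
        base = [rng.poisson(5, (4, 4)) for _ in range(2 * n)]
        for c in base:
            np.fill_diagonal(c, 0)
        shifted = [c.copy() for c in base[n:]]
        for c in shifted:
            c[0, 1] += 40  # strong effect on one unit
        g = GroupedTransitionSet(
            group_C=[_mat(c) for c in base[:n]],
            group_T=[_mat(c) for c in shifted])
        table = per_unit_tests(g)
        assert table.loc[table["p_adj"].idxmin(), "unit"] == "0->1"

    def test_family_excludes_unobserved_and_diagonal(self, rng):
        def one(v):
            c = np.zeros((3, 3), int)
            c[0, 1] = v
            return _mat(c)

        g = GroupedTransitionSet(group_C=[one(v) for v in (4, 5, 6)],
                                 group_T=[one(v) for v in (8, 9, 10)])
        table = per_unit_tests(g)
        assert table["unit"].tolist() == ["0->1"]


class TestBFL:
    def test_hand_worked_toy(self):
        # two-cluster matrices, hand-computed leave-one-out medians
        A = [_mat([[0, 2], [4, 0]], "a0"), _mat([[0, 4], [6, 0]], "a1"),
             _mat([[0, 6], [8, 0]], "a2")]
        B = [_mat([[0, 20], [22, 0]], "b0"), _mat([[0, 24], [26, 0]], "b1")]
        g = GroupedTransitionSet(group_C=A, group_T=B)
        scores = {s.sample_id: s for s in bfl_scores(g)}
        # for a0: M_A = median(a1, a2) = [[0,5],[7,0]], M_B = [[0,22],[24,0]]
        s = scores["a0"]
        assert s.d_A == pytest.approx(abs(2 - 5) + abs(4 - 7))
        assert s.d_B == pytest.approx(abs(2 - 22) + abs(4 - 24))
        assert s.score == pytest.approx(math.log(6 / 40))

    def test_equidistant_sample_scores_zero(self):
        # a0 sits exactly between M_A = [[0,4],[0,0]] and M_B = [[0,8],[0,0]]
        A = [_mat([[0, 6], [0, 0]], "a0"), _mat([[0, 4], [0, 0]], "a1"),
             _mat([[0, 4], [0, 0]], "a2")]
        B = [_mat([[0, 8], [0, 0]], "b0"), _mat([[0, 8], [0, 0]], "b1")]
        g = GroupedTransitionSet(group_C=A, group_T=B)
        s = {x.sample_id: x for x in bfl_scores(g)}["a0"]
        assert s.d_A == s.d_B == 2.0
        assert s.score == 0.0

    def test_scale_invariance(self, rng):
        mats = random_transition_matrices(rng, 8, nc=4, lam=6)
        g1 = GroupedTransitionSet(group_C=mats[:4], group_T=mats[4:])
        scaled = [_mat(m.counts * 3, m.recording_id) for m in mats]
        g2 = GroupedTransitionSet(group_C=scaled[:4], group_T=scaled[4:])
        s1 = [s.score for s in bfl_scores(g1)]
        s2 = [s.score for s in bfl_scores(g2)]
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_zero_distance_flagged_infinite(self):
        A = [_mat([[0, 2], [0, 0]], "a0"), _mat([[0, 2], [0, 0]], "a1"),
             _mat([[0, 2], [0, 0]], "a2")]
        B = [_mat([[0, 9], [0, 0]], "b0"), _mat([[0, 9], [0, 0]], "b1")]
        g = GroupedTransitionSet(group_C=A, group_T=B)
        s = {x.sample_id: x for x in bfl_scores(g)}["a0"]
        assert s.degenerate and s.score == -np.inf


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d_from_bfl([0, 1, 0, 1], ["a", "a", "b", "b"]) == 0.0

    def test_hand_sized_groups(self):
        # groups {0,1} and {2,3}: pooled sd = sqrt(0.5), d = 2/sqrt(0.5)
        d = cohens_d_from_bfl([0, 1, 2, 3], ["a", "a", "b", "b"])
        assert d == pytest.approx(2 / math.sqrt(0.5))

    def test_large_sample_standard_normal_shift(self, rng):
        a = rng.normal(0, 1, 10000)
        b = rng.normal(1, 1, 10000)
        d = cohens_d_from_bfl(np.r_[a, b], ["a"] * 10000 + ["b"] * 10000)
        assert d == pytest.approx(1.0, abs=0.05)


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        pc = power_curve(0.0, alpha=0.05)
        np.testing.assert_allclose(pc.power, 0.05, atol=1e-6)

    def test_monotone_in_n_and_effect(self):
        pc = power_curve(0.8)
        assert (np.diff(pc.power) >= -1e-12).all()
        small = power_curve(0.3).power
        large = power_curve(1.0).power
        assert (large >= small - 1e-12).all()

    def test_matches_monte_carlo_rejection_rates(self, rng):
        d, n, reps = 1.0, 12, 10000
        rejections = 0
        a = rng.normal(0, 1, (reps, n))
        b = rng.normal(d, 1, (reps, n))
        _, p = sps.ttest_ind(a, b, axis=1)
        rejections = (p < 0.05).mean()
        pc = power_curve(d, n_grid=(n,))
        assert pc.power[0] == pytest.approx(rejections, abs=0.02)


class TestResponderStratification:
    def test_boundary_value_is_nonresponder(self):
        out = stratify_responders([3.0], [1.0, 2.0, 3.0])
        assert out.tolist() == ["nonresponder"]

    def test_beyond_extremes_is_responder(self):
        out = stratify_responders([-5.0, 9.0, 1.5], [1.0, 2.0])
        assert out.tolist() == ["responder", "responder", "nonresponder"]

    def test_matches_brute_force_interval_check(self, rng):
        t = rng.normal(0, 2, 50)
        c = rng.normal(0, 1, 15)
        out = stratify_responders(t, c)
        for ti, lab in zip(t, out):
            expected = "nonresponder" if c.min() <= ti <= c.max() else "responder"
            assert lab == expected

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            stratify_responders([1.0], [])


class TestSensitivityAssay:
    def test_full_size_replicates_identical(self, rng):
        mats = random_transition_matrices(rng, 10, nc=3)
        g = GroupedTransitionSet(group_C=mats[:5], group_T=mats[5:])
        df = sensitivity_assay(g, sizes=(5,), reps=8, n_perm=100, seed=0)
        # no subsampling variability in the subset itself; spread only from
        # permutation seeds, so sd stays small relative to a resampled size
        assert len(df) == 1 and df["size"].iloc[0] == 5

    def test_oversized_request_skipped(self, rng):
        mats = random_transition_matrices(rng, 8, nc=3)
        g = GroupedTransitionSet(group_C=mats[:4], group_T=mats[4:])
        with pytest.warns(UserWarning, match="skipped"):
            df = sensitivity_assay(g, sizes=(25, 4), reps=3, n_perm=50, seed=0)
        assert df["size"].tolist() == [4]


class TestDoseModel:
    def test_exact_power_law_recovered(self):
        doses = np.array([1.0, 2.0, 4.0, 8.0])
        counts = 3.0 * doses ** 1.7
        fit = log_linear_dose_model(doses, counts)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.7)
        assert fit.intercept == pytest.approx(math.log(3.0))

    def test_r2_equals_f_over_f_plus_df2(self, rng):
        doses = np.repeat([1, 2, 3, 4, 6], 4).astype(float)
        counts = np.exp(0.5 * np.log(doses) + rng.normal(0, 0.3, 20))
        fit = log_linear_dose_model(doses, counts)
        assert fit.r_squared == pytest.approx(
            fit.f_stat / (fit.f_stat + fit.df[1]), rel=1e-12)

    def test_matches_closed_form_least_squares(self, rng):
        doses = rng.uniform(0.5, 8, 15)
        counts = rng.uniform(1, 50, 15)
        fit = log_linear_dose_model(doses, counts)
        x, y = np.log(doses), np.log(counts)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_zeros_excluded_and_counted(self):
        fit = log_linear_dose_model([1, 2, 3, 4, 0], [2, 3, 4, 5, 9])
        assert fit.n_used == 4 and fit.n_excluded == 1

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            log_linear_dose_model([1, 2], [1, 2])
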