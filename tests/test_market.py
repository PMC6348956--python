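"""Partner diversity, gRI, within-bout regression and rank-related trade tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracles
from conftest import make_log, random_directed_matrix
from groomtrade.dominance import DominanceResult
from groomtrade.errors import AnalysisError
from groomtrade.market import (
    gri,
    grooming_diversity,
    partner_choice_stability,
    received_given_vs_rank,
    reciprocity_family,
    reciprocity_vs_rank_distance,
    tolerance_correlation,
    up_hierarchy_test,
    within_bout_regression,
)
from groomtrade.matrices import DirectedInteractionMatrix
from groomtrade.obslog import segment_bouts


def dmatrix(arr, labels=None, kind="effort"):
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"a{i}" for i in range(arr.shape[0])]
    return DirectedInteractionMatrix(
        pd.DataFrame(arr, index=labels, columns=labels), kind
    )


def dominance_of(order):
    n = len(order)
    return DominanceResult(
        table=pd.DataFrame(
            {"adi": [(n - r) / (n - 1) for r in range(1, n + 1)], "rank": range(1, n + 1)},
            index=order,
        )
    )


class TestDiversity:
    def test_single_partner_scores_zero(self):
        x = np.zeros((7, 7))
        x[0, 1] = 12.0
        res = grooming_diversity(dmatrix(x, kind="frequency"))
        assert res.h_prime("a0") == 0.0

    def test_uniform_grooming_scores_one(self):
        x = np.zeros((7, 7))
        x[0, 1:] = 3.0
        res = grooming_diversity(dmatrix(x, kind="frequency"))
        assert res.h_prime("a0") == pytest.approx(1.0)

    def test_two_equal_partners_closed_form(self):
        x = np.zeros((7, 7))
        x[0, 1] = x[0, 2] = 5.0
        res = grooming_diversity(dmatrix(x, kind="frequency"))
        assert res.h_prime("a0") == pytest.approx(math.log(2) / math.log(6))

    def test_no_grooming_given_scores_zero(self):
        res = grooming_diversity(dmatrix(np.zeros((7, 7)), kind="frequency"))
        assert (res.table["h_prime"] == 0).all()

    @settings(derandomize=True, max_examples=40)
    @given(
        weights=st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=5
        )
    )
    def test_h_prime_bounded_for_any_distribution(self, weights):
        """H' always lies in [0, 1], hitting 0 iff at most one partner."""
        x = np.zeros((6, 6))
        x[0, 1 : 1 + len(weights)] = weights
        h = grooming_diversity(dmatrix(x, kind="frequency")).h_prime("a0")
        assert 0.0 <= h <= 1.0 + 1e-12
        if len(weights) == 1:
            assert h == 0.0

    def test_scale_and_permutation_invariance(self, rng):
        x = np.zeros((6, 6))
        x[0, 1:] = rng.uniform(1, 10, size=5)
        h1 = grooming_diversity(dmatrix(x, kind="frequency")).h_prime("a0")
        h2 = grooming_diversity(dmatrix(x * 7.3, kind="frequency")).h_prime("a0")
        x_perm = x.copy()
        x_perm[0, 1:] = rng.permutation(x[0, 1:])
        h3 = grooming_diversity(dmatrix(x_perm, kind="frequency")).h_prime("a0")
        assert h1 == pytest.approx(h2) == pytest.approx(h3)

    def test_too_few_females_rejected(self):
        with pytest.raises(AnalysisError):
            grooming_diversity(dmatrix(np.zeros((7, 7)), kind="frequency"), n_females=2)


class TestGri:
    def test_balanced_dyad_is_one(self):
        x = np.zeros((3, 3))
        x[0, 1] = x[1, 0] = 150.0
        g = gri(dmatrix(x))
        assert g.iloc[0, 1] == pytest.approx(1.0)

    def test_unidirectional_dyad_is_zero(self):
        x = np.zeros((3, 3))
        x[0, 1] = 200.0
        g = gri(dmatrix(x))
        assert g.iloc[0, 1] == pytest.approx(0.0)
        assert g.iloc[1, 0] == pytest.approx(0.0)

    def test_three_to_one_ratio(self):
        x = np.zeros((3, 3))
        x[0, 1], x[1, 0] = 300.0, 100.0
        assert gri(dmatrix(x)).iloc[0, 1] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        gab=st.floats(min_value=0.0, max_value=1e6),
        gba=st.floats(min_value=0.0, max_value=1e6),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_gri_properties_hold_for_any_durations(self, gab, gba, scale):
        """gRI is symmetric, scale-invariant and equals 1 - |a-b|/(a+b)."""
        x = np.zeros((3, 3))
        x[0, 1], x[1, 0] = gab, gba
        g = gri(dmatrix(x)).to_numpy()
        if gab + gba == 0:
            assert np.isnan(g[0, 1])
            return
        expected = 1.0 - abs(gab - gba) / (gab + gba)
        assert g[0, 1] == pytest.approx(expected)
        assert g[1, 0] == pytest.approx(g[0, 1])
        g_scaled = gri(dmatrix(x * scale)).to_numpy()
        assert g_scaled[0, 1] == pytest.approx(g[0, 1], abs=1e-9)
        assert 0.0 <= g[0, 1] <= 1.0

    def test_untraded_dyads_undefined(self):
        g = gri(dmatrix(np.zeros((3, 3))))
        assert g.isna().all().all()

    def test_symmetry_scale_invariance_and_closed_form(self, rng):
        x = random_directed_matrix(rng, 5, zero_frac=0.3).to_numpy()
        g1 = gri(dmatrix(x))
        g2 = gri(dmatrix(3.7 * x))
        pd.testing.assert_frame_equal(g1, g2)
        arr = g1.to_numpy()
        np.testing.assert_allclose(arr, arr.T, equal_nan=True)
        for i in range(5):
            for j in range(5):
                if i != j and x[i, j] + x[j, i] > 0:
                    expected = 1 - abs(x[i, j] - x[j, i]) / (x[i, j] + x[j, i])
                    assert arr[i, j] == pytest.approx(expected)


class TestWithinBoutRegression:
    @staticmethod
    def bouts_from(pairs):
        """pairs: list of (groomer, reciprocator, d1, d2, t0)."""
        rows = []
        for groomer, recip, d1, d2, t0 in pairs:
            rows.append(("grooming", groomer, recip, t0, d1))
            if d2 > 0:
                rows.append(("grooming", recip, groomer, t0 + d1 + 5.0, d2))
        return segment_bouts(make_log(rows))

    def test_perfect_reciprocation_degenerate(self):
        bouts = self.bouts_from(
            [("A", "B", 10.0, 10.0, 0.0), ("A", "B", 20.0, 20.0, 500.0),
             ("C", "D", 30.0, 30.0, 0.0)]
        )
        res = within_bout_regression(bouts)
        assert res.slope == pytest.approx(1.0)
        assert res.s2 == pytest.approx(0.0, abs=1e-12)
        assert res.degenerate

    def test_dyad_weights_sum_to_one(self):
        bouts = self.bouts_from(
            [("A", "B", 10.0, 9.0, t) for t in (0.0, 500.0, 1000.0, 1500.0)]
            + [("C", "D", 30.0, 20.0, 0.0)]
        )
        res = within_bout_regression(bouts)
        ab = res.weights[res.weights.index == "A|B"]
        assert len(ab) == 4 and (ab == 0.25).all()
        assert res.weights.groupby(level=0).sum().eq(1.0).all()

    def test_matches_normal_equations_oracle(self, rng):
        pairs = []
        t = 0.0
        dyads = [("A", "B"), ("C", "D"), ("E", "F"), ("A", "C")]
        for k in range(24):
            g, r = dyads[k % 4]
            d1 = float(rng.uniform(5, 60))
            d2 = d1 * float(rng.uniform(0.3, 1.8))
            pairs.append((g, r, d1, d2, t))
            t += 2000.0
        bouts = self.bouts_from(pairs)
        res = within_bout_regression(bouts)
        x = np.array([math.log(p[2]) for p in pairs])
        y = np.array([math.log(p[3]) for p in pairs])
        counts = {d: sum(1 for p in pairs if (p[0], p[1]) == d) for d in dyads}
        w = np.array([1.0 / counts[(p[0], p[1])] for p in pairs])
        slope, intercept, s2, f_stat = oracles.wls_normal_equations(x, y, w)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.s2 == pytest.approx(s2, abs=1e-10)
        assert res.f_stat == pytest.approx(f_stat, rel=1e-8)
        assert res.df == (1, 22)

    def test_too_few_reciprocated_bouts_rejected(self):
        bouts = self.bouts_from([("A", "B", 10.0, 8.0, 0.0)])
        with pytest.raises(AnalysisError, match="fewer than 3"):
            within_bout_regression(bouts)


class TestUpHierarchy:
    def test_alpha_expected_zero_and_lowest_expected_total(self):
        order = list("abcde")
        x = np.zeros((5, 5))
        x[0, 1] = 50.0  # alpha grooms down
        x[4, 0] = 30.0  # lowest grooms the alpha
        x[4, 3] = 10.0
        eff = dmatrix(x, labels=order)
        res = up_hierarchy_test(eff, eff, dominance_of(order))
        assert res.table.loc[("a", "effort"), "expected_up"] == 0.0
        assert res.table.loc[("a", "effort"), "observed_up"] == 0.0
        assert res.table.loc[("e", "effort"), "expected_up"] == pytest.approx(40.0)
        assert res.table.loc[("e", "effort"), "observed_up"] == pytest.approx(40.0)

    def test_hand_computed_toy_and_enumeration_oracle(self):
        order = list("abcd")
        x = np.array(
            [
                [0.0, 10.0, 0.0, 0.0],
                [20.0, 0.0, 6.0, 0.0],
                [8.0, 4.0, 0.0, 2.0],
                [5.0, 0.0, 3.0, 0.0],
            ]
        )
        eff = dmatrix(x, labels=order)
        res = up_hierarchy_test(eff, eff, dominance_of(order))
        # b gives 26 total, 1 of 3 females above: expected 26/3; observed 20
        assert res.table.loc[("b", "effort"), "expected_up"] == pytest.approx(26 / 3)
        assert res.table.loc[("b", "effort"), "observed_up"] == pytest.approx(20.0)
        # c gives 14 total, 2 of 3 above: expected 28/3; observed 12
        assert res.table.loc[("c", "effort"), "expected_up"] == pytest.approx(28 / 3)
        diff = res.table.xs("effort", level="measure")["difference"].to_numpy()
        assert res.wilcoxon_p["effort"] == pytest.approx(oracles.wilcoxon_exact_p(diff))

    def test_grooming_conserved_between_up_and_down(self, rng):
        order = [f"f{i}" for i in range(6)]
        x = random_directed_matrix(rng, 6, labels=order).to_numpy()
        eff = dmatrix(x, labels=order)
        res = up_hierarchy_test(eff, eff, dominance_of(order))
        up = res.table.xs("effort", level="measure")["observed_up"].sum()
        total = x.sum()
        # every directed cell is either up (recipient ranked higher) or down:
        # with labels ordered by rank, "up" cells are exactly the lower triangle
        expected_up = sum(x[i, j] for i in range(6) for j in range(6) if j < i)
        assert up == pytest.approx(expected_up)
        assert up <= total and total - up == pytest.approx(
            sum(x[i, j] for i in range(6) for j in range(6) if j > i)
        )

    def test_exclusion_rerun(self):
        order = list("abcde")
        x = np.abs(np.random.default_rng(4).normal(20, 5, size=(5, 5)))
        np.fill_diagonal(x, 0.0)
        eff = dmatrix(x, labels=order)
        res = up_hierarchy_test(eff, eff, dominance_of(order), exclude=["e"])
        assert res.excluded == ["e"]
        assert {f for f, _ in res.table.index} == set("abcd")

    def test_too_few_females_rejected(self):
        order = list("abc")
        eff = dmatrix(np.ones((3, 3)) - np.eye(3), labels=order)
        with pytest.raises(AnalysisError):
            up_hierarchy_test(eff, eff, dominance_of(order))


class TestReceivedGivenVsRank:
    def test_all_equal_ratios_tied(self):
        order = list("abcd")
        x = np.ones((4, 4)) - np.eye(4)
        res = received_given_vs_rank(dmatrix(x, labels=order), dominance_of(order))
        assert res.tied and math.isnan(res.rho)

    def test_received_increasing_with_rank_gives_rho_one(self):
        order = list("abcde")
        x = np.zeros((5, 5))
        for j, ind in enumerate(order):
            x[(j + 1) % 5, j] = 100.0 - 10.0 * j  # higher rank receives more
            x[j, (j + 1) % 5] += 10.0  # everyone gives a bit
        eff = dmatrix(x, labels=order)
        given = x.sum(axis=1)
        received = x.sum(axis=0)
        ratios = received / given
        assert (np.argsort(-ratios) == np.arange(5)).all()
        res = received_given_vs_rank(eff, dominance_of(order))
        assert res.rho == pytest.approx(1.0)

    def test_isolated_female_conventions(self):
        order = list("abcd")
        x = np.zeros((4, 4))
        x[0, 1] = x[1, 0] = 10.0
        x[2, 1] = 5.0
        eff = dmatrix(x, labels=order)
        res = received_given_vs_rank(eff, dominance_of(order))
        assert res.excluded == ["d"] and res.n == 3
        res0 = received_given_vs_rank(eff, dominance_of(order), zero_convention="zero")
        assert res0.n == 4 and res0.ratios["d"] == 0.0

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        order = [f"f{i}" for i in range(7)]
        x = random_directed_matrix(rng, 7, labels=order).to_numpy()
        eff = dmatrix(x, labels=order)
        res = received_given_vs_rank(eff, dominance_of(order))
        ratios = x.sum(axis=0) / x.sum(axis=1)
        inv_rank = 8 - np.arange(1, 8)
        expected = np.corrcoef(rankdata(ratios), rankdata(inv_rank))[0, 1]
        assert res.rho == pytest.approx(expected)


class TestMatrixCorrelationWrappers:
    def test_gri_inverse_of_rank_distance_gives_minus_one(self):
        order = list("abcde")
        d = np.abs(np.subtract.outer(np.arange(5), np.arange(5))).astype(float)
        g = 1.0 / (1.0 + d)
        np.fill_diagonal(g, np.nan)
        gf = pd.DataFrame(g, index=order, columns=order)
        df = pd.DataFrame(d, index=order, columns=order)
        res = reciprocity_vs_rank_distance(gf, df, n_perm=1000, seed=0)
        assert res.tau_kr == pytest.approx(-1.0)

    def test_sparse_gri_rejected(self):
        order = list("abcd")
        g = pd.DataFrame(np.nan, index=order, columns=order)
        g.iloc[0, 1] = g.iloc[1, 0] = 0.5
        d = pd.DataFrame(1.0, index=order, columns=order)
        with pytest.raises(AnalysisError, match="too few"):
            reciprocity_vs_rank_distance(g, d, n_perm=1000, seed=0)

    def test_hand_built_case_matches_loop_oracle(self, rng):
        order = list("wxyz")
        g = random_directed_matrix(rng, 4, labels=order)
        g.iloc[1, 3] = np.nan
        d = random_directed_matrix(rng, 4, labels=order, integers=True)
        res = reciprocity_vs_rank_distance(g, d, n_perm=1000, seed=0)
        kr_o, tau_o = oracles.taukr_statistic_loops(g.to_numpy(), d.to_numpy())
        assert res.kr == pytest.approx(kr_o) and res.tau_kr == pytest.approx(tau_o)

    def test_tolerance_direction(self, rng):
        x = random_directed_matrix(rng, 5)
        groom = dmatrix(x.to_numpy(), labels=list(x.index))
        # agonism as a positive monotone transform of grooming -> +1
        agon = dmatrix(np.sqrt(x.to_numpy()), labels=list(x.index), kind="agonism")
        res = tolerance_correlation(groom, agon, n_perm=1000, seed=0)
        assert res.tau_kr == pytest.approx(1.0)

    def test_partner_stability_identical_and_complementary(self, rng):
        base = (random_directed_matrix(rng, 6, zero_frac=0.4).to_numpy() > 0).astype(float)
        # keep rows informative: ensure each row has a 0 and a 1 off-diagonal
        for i in range(6):
            base[i, (i + 1) % 6] = 1.0
            base[i, (i + 2) % 6] = 0.0
        np.fill_diagonal(base, 0.0)
        labels = [f"f{i}" for i in range(6)]
        b1 = dmatrix(base, labels=labels, kind="binary")
        res_same = partner_choice_stability(b1, b1, labels, n_perm=1000, seed=0)
        assert res_same.tau_kr == pytest.approx(1.0)
        comp = 1.0 - base
        np.fill_diagonal(comp, 0.0)
        b2 = dmatrix(comp, labels=labels, kind="binary")
        res_comp = partner_choice_stability(b1, b2, labels, n_perm=1000, seed=0)
        assert res_comp.tau_kr == pytest.approx(-1.0)

    def test_partner_stability_needs_three_common(self, rng):
        b = dmatrix((random_directed_matrix(rng, 4).to_numpy() > 0).astype(float) - 0, kind="binary")
        with pytest.raises(AnalysisError, match="common"):
            partner_choice_stability(b, b, ["a0", "a1"], n_perm=1000, seed=0)


class TestReciprocityFamily:
    def test_family_carries_adjusted_alpha(self, rng):
        rows = []
        t = 0.0
        for k in range(30):
            a, b = ("A", "B") if k % 2 else ("B", "C")
            rows.append(("grooming", a, b, t, float(rng.uniform(5, 30))))
            if rng.random() < 0.5:
                rows.append(("grooming", b, a, t + 31.0 + 29.0, 5.0))
            t += 500.0
        from groomtrade.obslog import segment_bouts as seg

        bouts = seg(make_log(rows))
        fam = reciprocity_family(bouts, ["A", "B", "C"], n_perm=1000, seed=0)
        assert set(fam) == {
            "effort_full", "frequency_full", "effort_excluded", "frequency_excluded"
        }
        assert all(v["alpha_adjusted"] == 0.025 for v in fam.values())
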