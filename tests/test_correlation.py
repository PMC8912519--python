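"""Concordance counting, the (C-D)/(C+D) statistic, permutation nulls and
BH FDR — each checked against an independent naive oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cooccurnet import correlation as corr
from conftest import make_table


def naive_concordance(x, y):
    """Independent oracle: classify every index pair with a double loop."""
    n = len(x)
    C = D = Tx = Ty = Txy = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[j] > x[i]) - int(x[j] < x[i])
            dy = int(y[j] > y[i]) - int(y[j] < y[i])
            if dx == 0 and dy == 0:
                Txy += 1
            elif dx == 0:
                Tx += 1
            elif dy == 0:
                Ty += 1
            elif dx == dy:
                C += 1
            else:
                D += 1
    return C, D, Tx, Ty, Txy


class TestConcordanceCounts:
    def test_perfect_concordance(self):
        c = corr.concordance_counts([1, 2, 3], [1, 2, 3])
        assert (c.C, c.D) == (3, 0)

    def test_perfect_discordance(self):
        c = corr.concordance_counts([1, 2, 3], [3, 2, 1])
        assert (c.C, c.D) == (0, 3)

    def test_enumerated_example(self):
        c = corr.concordance_counts([1, 2, 3, 4], [2, 1, 4, 3])
        assert (c.C, c.D) == (4, 2)

    def test_matches_naive_oracle_including_heavy_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(3, 31))
            if rng.random() < 0.5:
                # heavy zero-ties, as in microbiome abundance vectors
                x = rng.choice([0.0, 0.0, 0.0, 1.0, 2.0], size=n)
                y = rng.choice([0.0, 0.0, 1.0, 3.0], size=n)
            else:
                x, y = rng.normal(size=n), rng.normal(size=n)
            c = corr.concordance_counts(x, y)
            assert (c.C, c.D, c.Tx, c.Ty, c.Txy) == naive_concordance(x, y)

    def test_partition_sums_to_all_pairs(self):
        c = corr.concordance_counts([0, 0, 1, 2, 2], [1, 1, 1, 0, 3])
        assert c.C + c.D + c.Tx + c.Ty + c.Txy == 10

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            corr.concordance_counts([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            corr.concordance_counts([1, 2], [1, 2])


class TestAssociationStatistic:
    def test_maximum(self):
        c = corr.ConcordanceCounts(C=3, D=0, Tx=0, Ty=0, Txy=0, n=3)
        assert corr.association_statistic(c, "gamma_paper") == 1.0

    def test_enumerated_arithmetic(self):
        c = corr.concordance_counts([1, 2, 3, 4], [2, 1, 4, 3])
        assert corr.association_statistic(c, "gamma_paper") == pytest.approx(1 / 3)

    def test_tie_handling_divergence(self):
        # C=2, D=0, Tx=1: gamma ignores the tie, tau_b does not
        c = corr.ConcordanceCounts(C=2, D=0, Tx=1, Ty=0, Txy=0, n=3)
        assert corr.association_statistic(c, "gamma_paper") == 1.0
        tau_b = corr.association_statistic(c, "tau_b")
        assert tau_b == pytest.approx((2 - 0) / math.sqrt(3 * 2))
        assert tau_b < 1.0

    def test_degenerate_pair_is_named_error(self):
        c = corr.concordance_counts([1.0, 1.0, 1.0], [2.0, 5.0, 3.0])
        with pytest.raises(corr.DegeneratePairError):
            corr.association_statistic(c, "gamma_paper")

    def test_untied_gamma_equals_tau_b_and_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.permutation(20).astype(float)
            y = rng.permutation(20).astype(float)
            c = corr.concordance_counts(x, y)
            gamma = corr.association_statistic(c, "gamma_paper")
            tau_b = corr.association_statistic(c, "tau_b")
            assert gamma == pytest.approx(tau_b, abs=1e-12)
            assert gamma == pytest.approx(
                stats.kendalltau(x, y).statistic, abs=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=15))
    def test_symmetry_and_monotone_invariance(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.normal(size=len(xs))
        x = np.asarray(xs)
        cx = corr.concordance_counts(x, y)
        if cx.C + cx.D == 0:
            return
        g_xy = corr.association_statistic(cx)
        g_yx = corr.association_statistic(corr.concordance_counts(y, x))
        assert g_xy == pytest.approx(g_yx, abs=1e-12)
        # increasing, tie-preserving transforms leave the statistic unchanged
        g_t = corr.association_statistic(
            corr.concordance_counts(stats.rankdata(x), 3.0 * y + 7.0)
        )
        assert g_xy == pytest.approx(g_t, abs=1e-12)


def naive_exact_p(x, y, method="gamma_paper"):
    """Second, naive full-enumeration implementation (float arithmetic)."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def stat(a, b):
        C, D, Tx, Ty, Txy = naive_concordance(a, b)
        if method == "gamma_paper":
            return math.inf if C + D == 0 else (C - D) / (C + D)
        den = math.sqrt((C + D + Tx) * (C + D + Ty))
        return math.inf if den == 0 else (C - D) / den

    obs = abs(stat(x, y))
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(stat(x, y[list(perm)])) >= obs - 1e-12:
            count += 1
    return count / total


class TestExactPValue:
    def test_n3_perfect_concordance(self):
        # of the 3! = 6 permutations one gives +1 and one gives -1
        assert corr.exact_p_value([1, 2, 3], [1, 2, 3]) == pytest.approx(2 / 6)

    def test_constant_vector_is_degenerate_before_p(self):
        with pytest.raises(corr.DegeneratePairError):
            corr.exact_p_value([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("method", ["gamma_paper", "tau_b"])
    def test_matches_naive_enumeration_oracle(self, method):
        rng = np.random.default_rng(3)
        for n in (5, 6):
            for _ in range(3):
                x, y = rng.normal(size=n), rng.normal(size=n)
                assert corr.exact_p_value(x, y, method) == pytest.approx(
                    naive_exact_p(x, y, method), abs=1e-12
                )

    def test_matches_naive_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(4):
            x = rng.choice([0.0, 0.0, 1.0, 2.0], size=6)
            y = rng.choice([0.0, 1.0, 1.0, 3.0], size=6)
            if corr.concordance_counts(x, y).C + corr.concordance_counts(x, y).D == 0:
                continue
            assert corr.exact_p_value(x, y) == pytest.approx(
                naive_exact_p(x, y), abs=1e-12
            )

    def test_matches_scipy_exact_for_untied_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.permutation(7).astype(float)
            y = rng.permutation(7).astype(float)
            ours = corr.exact_p_value(x, y, "tau_b")
            scipy_p = stats.kendalltau(x, y, method="exact").pvalue
            assert ours == pytest.approx(scipy_p, abs=1e-12)

    def test_large_n_routes_to_named_condition(self):
        x, y = np.arange(9.0), np.arange(9.0)
        with pytest.raises(corr.SampleSizeTooLargeError):
            corr.exact_p_value(x, y)
        p, kind = corr.permutation_p_value(x, y, seed=1)
        assert kind == "monte_carlo" and 0 < p <= 1

    def test_super_uniform_null_at_n5(self):
        """P(p <= alpha) <= alpha at every achievable alpha, by full
        enumeration of all 5! null orderings of an untied vector."""
        x = np.arange(5, dtype=float)
        p_values = sorted(
            corr.exact_p_value(x, np.array(perm, dtype=float))
            for perm in itertools.permutations(range(5))
        )
        p_arr = np.array(p_values)
        for alpha in sorted(set(p_values)):
            assert (p_arr <= alpha).mean() <= alpha + 1e-12


class TestMonteCarloPValue:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p1 = corr.monte_carlo_p_value(x, y, seed=77)
        p2 = corr.monte_carlo_p_value(x, y, seed=77)
        assert p1 == p2

    def test_minimal_attainable_p_for_extreme_case(self):
        x = np.arange(20, dtype=float)
        p = corr.monte_carlo_p_value(x, x, n_permutations=9999, seed=0)
        assert p == pytest.approx(1 / 10000, abs=2e-4)

    def test_within_three_se_of_exact(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=8), rng.normal(size=8)
        exact = corr.exact_p_value(x, y)
        n_perm = 9999
        mc = corr.monte_carlo_p_value(x, y, n_permutations=n_perm, seed=6)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= 3 * se + 2 / n_perm

    def test_rejects_too_few_permutations(self):
        with pytest.raises(ValueError):
            corr.monte_carlo_p_value([1, 2, 3], [1, 2, 3], n_permutations=10)


class TestBhFdr:
    def test_hand_worked_example(self):
        q = corr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(corr.bh_fdr([0.3]), [0.3])

    def test_empty_input(self):
        assert corr.bh_fdr([]).size == 0

    def test_step_up_definition_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = corr.bh_fdr(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            running = 1.0
            for rank_from_top in range(m, 0, -1):
                idx = order[rank_from_top - 1]
                running = min(running, p[idx] * m / rank_from_top)
                expected[idx] = running
            np.testing.assert_allclose(q, expected, atol=1e-12)
            assert np.all(q >= p - 1e-12)
            # monotone: sorting by p sorts q
            assert np.all(np.diff(q[order]) >= -1e-12)


class TestPairwiseAssociations:
    def _table(self, matrix, taxa):
        return make_table(np.asarray(matrix, float), taxa, value_kind="counts")

    def test_two_taxa_yield_one_association(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.uniform(1, 10, size=(6, 2)), ["a", "b"])
        res = corr.pairwise_associations(table, seed=0)
        assert len(res.associations) == 1
        assert res.associations[0].taxon_i == "a"

    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(8)
        table = self._table(rng.uniform(1, 10, size=(7, 5)), list("abcde"))
        res = corr.pairwise_associations(table, seed=0)
        assert len(res.associations) == 10
        assert res.degenerate == []

    def test_degenerate_taxa_recorded_with_reason(self):
        m = np.column_stack(
            [np.arange(1, 7), np.zeros(6), np.random.default_rng(0).uniform(1, 2, 6)]
        )
        table = self._table(m, ["live", "absent", "other"])
        res = corr.pairwise_associations(table, seed=0)
        degenerate_pairs = {(d[0], d[1]) for d in res.degenerate}
        assert ("live", "absent") in degenerate_pairs
        assert ("absent", "other") in degenerate_pairs
        assert len(res.associations) == 1

    def test_fdr_control_under_independent_null(self):
        """Fraction of q <= 0.05 calls among independent taxa stays near or
        below 0.05 on average (20 seeds, n = 8, 6 taxa)."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            table = self._table(rng.uniform(1, 10, size=(8, 6)), list("abcdef"))
            res = corr.pairwise_associations(table, seed=seed)
            q = np.array([a.q_value for a in res.associations])
            rates.append((q <= 0.05).mean())
        assert np.mean(rates) <= 0.05

    def test_sign_matches_tau(self):
        rng = np.random.default_rng(17)
        table = self._table(rng.uniform(1, 10, size=(8, 4)), list("abcd"))
        res = corr.pairwise_associations(table, seed=0)
        for a in res.associations:
            expected = (
                "co_occurrence" if a.tau > 0
                else "co_exclusion" if a.tau < 0 else "none"
            )
            assert a.sign == expected

    def test_round_trip_tsv(self, tmp_path):
        rng = np.random.default_rng(19)
        table = self._table(rng.uniform(1, 10, size=(6, 4)), list("abcd"))
        res = corr.pairwise_associations(table, seed=3)
        path = tmp_path / "assoc.tsv"
        corr.write_associations(res, path)
        back = corr.read_associations(path)
        assert len(back) == len(res.associations)
        for orig, rt in zip(res.associations, back):
            assert (orig.taxon_i, orig.taxon_j) == (rt.taxon_i, rt.taxon_j)
            assert orig.tau == pytest.approx(rt.tau)
            assert orig.q_value == pytest.approx(rt.q_value)
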