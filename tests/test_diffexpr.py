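"""Audic-Claverie test, Benjamini-Hochberg correction and differential calls.

Oracles: an exact-fraction factorial evaluation of the posterior-predictive
pmf, brute-force tail summation, the equivalent scipy negative-binomial
parameterization, and a quadratic-time step-up implementation of BH.
"""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from memoryscan.diffexpr import (
    ac_log_pmf,
    ac_pmf,
    ac_test,
    ac_test_minlike,
    benjamini_hochberg,
    call_differential,
    deg_sets,
    read_results,
    write_results,
)
from memoryscan.expression import CountMatrix, GeneAnnotation, GeneModel, rpkm


def naive_pmf(y: int, x: int, ratio: Fraction) -> Fraction:
    """Exact p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) via integer factorials."""
    return (
        ratio**y
        * factorial(x + y)
        / (factorial(x) * factorial(y) * (1 + ratio) ** (x + y + 1))
    )


def naive_two_sided(x: int, y: int, ratio: Fraction, upper_limit: int = 4000) -> float:
    lower = sum(naive_pmf(k, x, ratio) for k in range(0, y + 1))
    upper = sum(naive_pmf(k, x, ratio) for k in range(y, upper_limit))
    return float(min(1, 2 * min(lower, upper)))


class TestPmf:
    def test_base_cases(self):
        assert ac_pmf(0, 0, 1.0) == pytest.approx(0.5)
        assert ac_pmf(1, 0, 1.0) == pytest.approx(0.25)

    def test_normalization(self):
        total = float(np.exp(ac_log_pmf(np.arange(0, 201), 5, 1.0)).sum())
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("ratio", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_matches_exact_factorial_evaluation(self, ratio):
        ys = np.arange(0, 16)
        for x in range(0, 16):
            got = np.exp(ac_log_pmf(ys, x, float(ratio)))
            expected = np.array([float(naive_pmf(int(y), x, ratio)) for y in ys])
            np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_matches_negative_binomial_parameterization(self):
        # p(y|x) is NB(x+1 successes, success prob 1/(1+r)) in y
        for x, ratio in [(0, 0.5), (3, 1.0), (10, 2.0), (25, 0.8)]:
            ys = np.arange(0, 80)
            got = np.exp(ac_log_pmf(ys, x, ratio))
            expected = scipy.stats.nbinom.pmf(ys, x + 1, 1.0 / (1.0 + ratio))
            np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac_pmf(-1, 0, 1.0)
        with pytest.raises(ValueError):
            ac_pmf(0, -2, 1.0)
        with pytest.raises(ValueError):
            ac_pmf(1, 1, 0.0)


class TestTwoSidedTest:
    def test_no_evidence_cases(self):
        assert ac_test(0, 0, 1e6, 1e6) == 1.0
        # equal counts in equal libraries: both tails cover the mode
        for x in [1, 5, 50, 500]:
            assert ac_test(x, x, 1e6, 1e6) == 1.0

    def test_extreme_discrepancy(self):
        assert ac_test(100, 0, 1e6, 1e6) < 1e-20

    @pytest.mark.parametrize(
        "x,y,ratio",
        [(0, 5, Fraction(1)), (3, 20, Fraction(1)), (10, 2, Fraction(1, 2)),
         (30, 30, Fraction(2)), (7, 0, Fraction(1)), (15, 45, Fraction(2))],
    )
    def test_matches_brute_force_tail_doubling(self, x, y, ratio):
        got = ac_test(x, y, 1e6, float(ratio) * 1e6)
        expected = naive_two_sided(x, y, ratio)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_negative_binomial_tails(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = int(rng.integers(0, 2000))
            y = int(rng.integers(0, 2000))
            n1, n2 = rng.integers(10**5, 10**7, size=2)
            r = n2 / n1
            lower = scipy.stats.nbinom.cdf(y, x + 1, 1.0 / (1.0 + r))
            upper = scipy.stats.nbinom.sf(y - 1, x + 1, 1.0 / (1.0 + r))
            expected = min(1.0, 2.0 * min(lower, upper))
            assert ac_test(x, y, n1, n2) == pytest.approx(expected, rel=1e-8, abs=1e-300)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x=st.integers(0, 300), y=st.integers(0, 300),
           n1=st.integers(10**4, 10**7), n2=st.integers(10**4, 10**7))
    def test_symmetric_under_library_exchange_up_to_point_mass(self, x, y, n1, n2):
        """Exchanging (x, N1) and (y, N2) changes the p-value by at most the
        observed-point masses: with inclusive tails on both sides the two
        orientations differ only in which single pmf term each tail counts
        (the beta-identity P(X' <= x | y, N1/N2) = P(Y > y | x, N2/N1) makes
        everything else cancel)."""
        forward = ac_test(x, y, n1, n2)
        backward = ac_test(y, x, n2, n1)
        slack = 2.0 * (ac_pmf(y, x, n2 / n1) + ac_pmf(x, y, n1 / n2)) + 1e-12
        assert abs(forward - backward) <= slack

    def test_monotone_in_departure_from_expectation(self):
        # p decreases as y moves away from its expectation x * N2/N1, both directions
        x, n1, n2 = 50, 1e6, 1e6
        ps_up = [ac_test(x, y, n1, n2) for y in range(50, 160, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [ac_test(x, y, n1, n2) for y in range(50, -1, -5)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_down, ps_down[1:]))

    def test_minlike_policy_tracks_doubling_within_factor_two(self):
        # minlike includes the whole observed-side tail (>= half the doubled
        # p) and can exceed doubling when the opposite tail holds many
        # individually-less-likely outcomes; it never exceeds twice it.
        for x, y in [(5, 20), (100, 40), (0, 8), (30, 30)]:
            p_min = ac_test_minlike(x, y, 1e6, 1e6)
            p_dbl = ac_test(x, y, 1e6, 1e6)
            assert p_dbl / 2 - 1e-12 <= p_min <= min(1.0, 2 * p_dbl + 1e-12)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """q_i = min over j with p_(j) >= p_i of m * p_(j) / j (step-up definition)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i] or ranks[j] >= ranks[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.05]).tolist() == [0.05]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_and_statsmodels(self):
        import statsmodels.stats.multitest as smm

        rng = np.random.default_rng(11)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = np.round(rng.random(m), 3)
            q = benjamini_hochberg(p)
            np.testing.assert_allclose(q, brute_force_bh(p), rtol=1e-12)
            np.testing.assert_allclose(q, smm.multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        direct = benjamini_hochberg(p)
        permuted = benjamini_hochberg(p[perm])
        unpermuted = np.empty_like(permuted)
        unpermuted[perm] = permuted
        np.testing.assert_allclose(direct, unpermuted, rtol=1e-12)

    def test_sorted_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])


class TestCallDifferential:
    @pytest.fixture
    def expr_counts(self, tiny_annotation, tiny_counts):
        return rpkm(tiny_counts, tiny_annotation), tiny_counts

    def test_null_contrast_no_calls(self, tiny_annotation):
        counts = pd.DataFrame(
            {"a": [100, 200, 50, 10], "b": [100, 200, 50, 10]},
            index=pd.Index(["Alpha", "Beta", "Gamma", "Delta"], name="gene_id"),
        )
        cm = CountMatrix(counts=counts, library_sizes=pd.Series({"a": 1e6, "b": 1e6}))
        expr = rpkm(cm, tiny_annotation)
        res = call_differential(expr, cm, "b", "a")
        up, down = deg_sets(res)
        assert up == set() and down == set()
        assert (res["p_raw"] == 1.0).all()

    def test_calls_respect_fold_and_significance(self, expr_counts):
        expr, counts = expr_counts
        res = call_differential(expr, counts, "tnf", "ctrl")
        # Alpha 1000 -> 4000 reads: fourfold up; Delta 400 -> 100: fourfold down
        assert res.loc["Alpha", "call"] == "up"
        assert res.loc["Alpha", "fold_change"] > 2
        assert res.loc["Delta", "call"] == "down"
        # Beta is below the presence floor in both samples -> not tested
        assert "Beta" not in res.index
        # Gamma induced from zero: finite, large fold change
        assert np.isfinite(res.loc["Gamma", "fold_change"])
        assert res.loc["Gamma", "fold_change"] > 2

    def test_up_down_disjoint_and_consistent(self, expr_counts):
        expr, counts = expr_counts
        res = call_differential(expr, counts, "tnf", "ctrl", use_adjusted=False)
        up, down = deg_sets(res)
        assert not up & down
        assert (res.loc[sorted(up), "fold_change"] >= 2).all()
        assert (res.loc[sorted(down), "fold_change"] <= 0.5).all()

    def test_unknown_sample_errors(self, expr_counts):
        expr, counts = expr_counts
        with pytest.raises(KeyError, match="missing"):
            call_differential(expr, counts, "missing", "ctrl")

    def test_results_round_trip(self, expr_counts, tmp_path):
        expr, counts = expr_counts
        res = call_differential(expr, counts, "tnf", "ctrl")
        write_results(res, tmp_path / "de.tsv")
        back = read_results(tmp_path / "de.tsv")
        assert deg_sets(back) == deg_sets(res)
        np.testing.assert_allclose(back["p_raw"], res["p_raw"])
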