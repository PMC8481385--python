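"""Hypergeometric/rank-sum enrichment testing against independent oracles."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clinenrich import (
    AttributeSpec,
    ClinotypeTable,
    CohortEnrichment,
    DiscretizationRule,
    ValidationError,
    bonferroni,
    cfea,
    hypergeom_pvalue,
    ranksum_pvalue,
    select_manual,
)


def hypergeom_tail_by_enumeration(k, n, K, N):
    """P(X >= k) by brute-force enumeration of all C(N, n) draws."""
    hits = total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def ranksum_two_sided_by_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([a, b])
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = [
        sum(1 for i in idx for j in range(len(pooled)) if j not in set(idx)
            and pooled[i] > pooled[j])
        for idx in itertools.combinations(range(len(pooled)), na)
    ]
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    return min(1.0, 2 * min(p_ge, p_le))


class TestHypergeomPvalue:
    def test_k_zero_gives_one(self):
        assert hypergeom_pvalue(0, 4, 5, 10) == 1.0

    def test_closed_form_worked_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_pvalue(4, 4, 5, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_cohort_equals_population_null(self):
        assert hypergeom_pvalue(7, 10, 7, 10) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_pvalue(5, 4, 5, 10)  # k > n
        with pytest.raises(ValidationError):
            hypergeom_pvalue(1, 4, 11, 10)  # K > N

    def test_matches_enumeration_on_small_grid(self):
        # spot-check the slow subset oracle (the full N<=12 sweep lives in
        # the acceptance suite)
        for N, n, K in [(6, 3, 2), (7, 4, 5), (8, 2, 6)]:
            for k in range(max(0, n - (N - K)), min(n, K) + 1):
                assert hypergeom_pvalue(k, n, K, N) == pytest.approx(
                    hypergeom_tail_by_enumeration(k, n, K, N), abs=1e-12
                )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_monotone_nonincreasing_in_k(self, data):
        N = data.draw(st.integers(2, 40))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        lo = max(0, n - (N - K))
        ps = [hypergeom_pvalue(k, n, K, N) for k in range(lo, min(n, K) + 1)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_binary_complement_mirror(self, data):
        # enrichment of level A with (k,n,K,N) mirrors level B with
        # (n-k, n, N-K, N): the two tails overlap only at the observed table
        N = data.draw(st.integers(2, 30))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(0, N))
        lo = max(0, n - (N - K))
        k = data.draw(st.integers(lo, min(n, K)))
        p_a = hypergeom_pvalue(k, n, K, N)
        p_b = hypergeom_pvalue(n - k, n, N - K, N)
        # P(X>=k) + P(X<=k) = 1 + P(X=k); the mirror restates the lower tail
        pmf = comb(K, k) * comb(N - K, n - k) / comb(N, n)
        assert p_a + p_b == pytest.approx(1 + pmf, rel=1e-9)


class TestRanksumPvalue:
    def test_exact_small_example(self):
        out = ranksum_pvalue([1.0, 2.0], [3.0, 4.0])
        assert out.mode == "exact"
        assert out.pvalue == pytest.approx(1 / 3)

    def test_exact_singleton_example(self):
        out = ranksum_pvalue([5.0], [1.0, 2.0, 3.0])
        assert out.mode == "exact"
        assert out.pvalue == pytest.approx(0.5)

    def test_identical_multisets_give_p_one(self):
        out = ranksum_pvalue([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.mode == "asymptotic"  # ties force the normal approximation
        assert out.pvalue == pytest.approx(1.0)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            ranksum_pvalue([], [1.0])

    def test_large_or_tied_inputs_use_asymptotic_mode(self):
        rng = np.random.default_rng(0)
        out = ranksum_pvalue(rng.normal(size=30), rng.normal(size=30))
        assert out.mode == "asymptotic"

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_exact_mode_matches_permutation_enumeration(self, data):
        na = data.draw(st.integers(1, 5))
        nb = data.draw(st.integers(1, 5))
        vals = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False),
                min_size=na + nb, max_size=na + nb, unique=True,
            )
        )
        a, b = np.array(vals[:na]), np.array(vals[na:])
        out = ranksum_pvalue(a, b)
        assert out.mode == "exact"
        assert out.pvalue == pytest.approx(
            ranksum_two_sided_by_enumeration(a, b), abs=1e-12
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 5, 0.05), (0.5, 10, 1.0), (0.37, 1, 0.37), (0.004, 5, 0.02)]
    )
    def test_min_one_m_p(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_domain_checks(self):
        with pytest.raises(ValidationError):
            bonferroni(0.0, 3)
        with pytest.raises(ValidationError):
            bonferroni(0.5, 0)


def _binary_table(flags, extra=None):
    n = len(flags)
    data = {"marker": ["pos" if f else "neg" for f in flags]}
    specs = [AttributeSpec("marker", "categorical", ("neg", "pos"))]
    if extra is not None:
        data.update(extra[0])
        specs.extend(extra[1])
    df = pd.DataFrame(data, index=pd.Index([f"P{i}" for i in range(n)], name="sample_id"))
    return ClinotypeTable(df, specs)


class TestCfea:
    def test_perfectly_concentrated_attribute(self):
        # 20 samples, 10 carriers; cohort = exactly the carriers
        table = _binary_table([i < 10 for i in range(20)])
        cohort = select_manual([f"P{i}" for i in range(10)], table)
        res = cfea(table, cohort)
        row = next(r for r in res.results if r.level == "pos")
        assert (row.k, row.n, row.K, row.N) == (10, 10, 10, 20)
        assert row.p_value == pytest.approx(1 / 184756, rel=1e-9)
        assert row.enriched_flag

    def test_cohort_equal_population_is_null_everywhere(self, small_table):
        cohort = select_manual(small_table.sample_ids, small_table)
        res = cfea(small_table, cohort)
        for r in res.results:
            if r.test == "hypergeometric":
                assert r.p_value == 1.0
            else:  # empty complement: untestable, reported without p
                assert math.isnan(r.p_value)
                assert r.mode == "untestable"
        assert len(res.enriched) == 0

    def test_missing_values_shrink_denominators(self):
        flags = [True] * 4 + [False] * 4
        extra = (
            {"age": [60.0, np.nan, 50.0, 55.0, 70.0, 65.0, np.nan, 75.0]},
            [AttributeSpec("age", "numerical")],
        )
        table = _binary_table(flags, extra)
        table.data.loc["P0", "marker"] = np.nan
        cohort = select_manual(["P0", "P1", "P2"], table)
        res = cfea(table, cohort)
        row = next(r for r in res.results if r.level == "pos")
        assert (row.n, row.N) == (2, 7)  # P0's missing marker drops out
        age = next(r for r in res.results if r.attribute == "age")
        assert (age.n, age.N) == (2, 6)  # two missing ages dropped

    def test_discretization_rules_applied_before_testing(self):
        rng = np.random.default_rng(7)
        surv = np.concatenate([rng.normal(450, 30, 12), rng.normal(150, 30, 12)])
        df = pd.DataFrame(
            {"survival": surv},
            index=pd.Index([f"P{i}" for i in range(24)], name="sample_id"),
        )
        table = ClinotypeTable(df, [AttributeSpec("survival", "numerical")])
        cohort = select_manual([f"P{i}" for i in range(12)], table)
        res = cfea(table, cohort, rules=[DiscretizationRule("survival", (300.0,))])
        tests = {(r.attribute, r.level) for r in res.results}
        assert ("Discrete_survival", ">=300") in tests
        assert ("survival", None) in tests
        assert res.m_tests == 3  # two discrete levels + one rank-sum

    def test_m_tests_counts_only_performed_tests(self):
        table = _binary_table(
            [True, False] * 3,
            ({"age": [np.nan, 60.0, np.nan, 61.0, np.nan, 62.0]},
             [AttributeSpec("age", "numerical")]),
        )
        cohort = select_manual(["P0", "P2", "P4"], table)  # cohort ages all missing
        res = cfea(table, cohort)
        age = next(r for r in res.results if r.attribute == "age")
        assert math.isnan(age.p_value)
        assert res.m_tests == 2  # the two marker levels only

    def test_adjusted_p_and_flags_consistent(self, small_table):
        cohort = select_manual(["P1", "P2"], small_table)
        res = cfea(small_table, cohort, alpha=0.05)
        for r in res.results:
            if not math.isnan(r.p_value):
                assert r.p_adjusted == pytest.approx(
                    bonferroni(r.p_value, res.m_tests)
                )
                assert r.enriched_flag == (r.p_adjusted < 0.05)

    def test_bh_adjustment_option(self):
        table = _binary_table([i < 10 for i in range(20)])
        cohort = select_manual([f"P{i}" for i in range(10)], table)
        res = cfea(table, cohort, adjustment="bh")
        assert res.run_metadata["adjustment"] == "bh"
        for r in res.results:
            assert r.p_adjusted >= r.p_value - 1e-15

    def test_two_sided_alternative_flags_depletion(self):
        table = _binary_table([i < 10 for i in range(20)])
        cohort = select_manual([f"P{i}" for i in range(10, 20)], table)  # all "neg"
        one_sided = cfea(table, cohort)
        two_sided = cfea(table, cohort, alternative="two-sided")
        pos_one = next(r for r in one_sided.results if r.level == "pos")
        pos_two = next(r for r in two_sided.results if r.level == "pos")
        assert pos_one.p_value == pytest.approx(1.0)  # depletion invisible one-sided
        assert pos_two.p_value < 0.001


class TestModelInterface:
    def test_from_dataframe_constructor(self):
        df = pd.DataFrame(
            {
                "pid": ["A", "B", "C", "D"],
                "sex": ["f", "m", "f", "m"],
                "age": ["60", "70", "50", "40"],
            }
        )
        model = CohortEnrichment.from_dataframe(df, ["A", "B"], id_column="pid")
        res = model.fit()
        assert res.m_tests == 3
        assert set(res.frame["attribute"]) == {"sex", "age"}

    def test_summary_mentions_key_quantities(self, small_table):
        cohort = select_manual(["P1", "P2"], small_table)
        res = CohortEnrichment(small_table, cohort).fit()
        text = res.summary()
        assert "Bonferroni" in text or "bonferroni" in text
        assert f"tests performed (Bonferroni m): {res.m_tests}" in text
        assert "p_adjusted" in text

    def test_cohort_outside_population_rejected(self, small_table):
        from clinenrich import Subcohort

        rogue = Subcohort(("P1", "ZZ"), {"mode": "manual"})
        with pytest.raises(ValidationError, match="ZZ"):
            CohortEnrichment(small_table, rogue)

    def test_alpha_domain_checked(self, small_table):
        cohort = select_manual(["P1"], small_table)
        with pytest.raises(ValidationError, match="alpha"):
            CohortEnrichment(small_table, cohort, alpha=1.5)
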