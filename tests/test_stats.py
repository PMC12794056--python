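import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afm.errors import DegenerateInputError, InsufficientGroupsError
from afm.stats import (
    compare_groups,
    independent_t,
    mann_whitney_u,
    summarize_group,
)

from _oracles import mwu_enumeration, welch_formula


class TestIndependentT:
    def test_identical_groups(self):
        t, p = independent_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_welch_matches_closed_form_example(self):
        # oracle-computed: t = -1/sqrt(5/12 + 5/12), Welch df = 6
        t, p = independent_t([1, 2, 3, 4], [2, 3, 4, 5], flavor="welch")
        assert t == pytest.approx(-1.0954451150103324, abs=1e-10)
        ot, op = welch_formula([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(ot, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_welch_matches_closed_form_random(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 30)).tolist()
            b = rng.normal(0.3, 2, rng.integers(2, 30)).tolist()
            t, p = independent_t(a, b, flavor="welch")
            ot, op = welch_formula(a, b)
            assert t == pytest.approx(ot, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [0.5, 2.5, 2.5, 4.0]
        t1, p1 = independent_t(a, b)
        t2, p2 = independent_t(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_equal_constants(self):
        with pytest.raises(DegenerateInputError):
            independent_t([2, 2, 2], [2, 2, 2])

    def test_degenerate_distinct_constants(self):
        t, p = independent_t([3, 3, 3], [1, 1, 1])
        assert t == np.inf and p == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shift=st.floats(-1e3, 1e3), seed=st.integers(0, 50))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(size=9)
        t1, p1 = independent_t(a, b)
        t2, p2 = independent_t(a + shift, b + shift)
        assert t1 == pytest.approx(t2, rel=1e-7)
        assert p1 == pytest.approx(p2, rel=1e-7)


class TestMannWhitneyU:
    def test_tiny_exact_example(self):
        # all 6 assignments of ranks {1..4} into groups of 2: U_a = 0 is the
        # single most extreme, so one-sided "less" p = 1/6
        u, p, method = mann_whitney_u([1, 2], [3, 4], alternative="less")
        assert u == 0.0 and method == "exact"
        assert p == pytest.approx(1 / 6, abs=1e-15)

    def test_identical_multisets_two_sided_p_one(self):
        u, p, method = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_matches_enumeration_6v6(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=6)
        u, p, method = mann_whitney_u(a, b)
        ou, op = mwu_enumeration(a, b, "two-sided")
        assert method == "exact"
        assert u == ou
        assert p == pytest.approx(op, abs=1e-12)
        # normal approximation should land near the exact answer
        _, p_approx, m2 = mann_whitney_u(a, b, exact_cutoff=0)
        assert m2 == "normal-approx"
        assert abs(p_approx - op) < 0.03

    def test_randomized_exact_vs_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            na = int(rng.integers(1, 7))
            nb = int(rng.integers(1, 13 - na))
            a, b = rng.normal(size=na), rng.normal(size=nb)
            alt = ["two-sided", "greater", "less"][int(rng.integers(3))]
            u, p, method = mann_whitney_u(a, b, alternative=alt)
            ou, op = mwu_enumeration(a, b, alt)
            assert method == "exact"
            assert u == ou and p == pytest.approx(op, abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        u, p, method = mann_whitney_u([1, 2, 2, 3], [2, 3, 3, 4])
        assert method == "normal-approx"
        assert 0 <= p <= 1

    def test_u_complement_identity(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(size=11)
        ua, _, _ = mann_whitney_u(a, b)
        ub, _, _ = mann_whitney_u(b, a)
        assert ua + ub == len(a) * len(b)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            mann_whitney_u([], [1, 2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(shift=st.floats(-1e3, 1e3), seed=st.integers(0, 40))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=7)
        u1, p1, _ = mann_whitney_u(a, b)
        u2, p2, _ = mann_whitney_u(a + shift, b + shift)
        assert u1 == u2 and p1 == pytest.approx(p2, rel=1e-12)


class TestSummarizeGroup:
    @pytest.mark.parametrize(
        "values,key,expected",
        [
            ([1, 2, 3, 4], "median", 2.5),
            ([7], "mean", 7),
            ([7], "iqr", 0),
            ([1, 1, 1, 100], "median", 1),
            ([1, 1, 1, 100], "mean", 25.75),
        ],
    )
    def test_examples(self, values, key, expected):
        assert summarize_group(values)[key] == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            summarize_group([])


class TestCompareGroups:
    def _frame(self, distal, proximal):
        import pandas as pd

        return pd.DataFrame(
            {
                "tubule_class": ["distal"] * len(distal) + ["proximal"] * len(proximal),
                "fibrotic_fraction": list(distal) + list(proximal),
            }
        )

    def test_means_in_percent(self):
        res = compare_groups(self._frame([0.30, 0.35, 0.40], [0.30, 0.32, 0.31, 0.29]))
        assert res.n_distal == 3 and res.n_proximal == 4
        assert res.mean_distal == pytest.approx(35.0)
        assert res.mean_proximal == pytest.approx(30.5)

    def test_all_equal_reports_null(self):
        res = compare_groups(self._frame([0.3, 0.3], [0.3, 0.3, 0.3]))
        assert res.t_statistic == 0.0 and res.p_t == 1.0
        assert res.p_u == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientGroupsError):
            compare_groups(self._frame([0.3, 0.4, 0.5], []))

    def test_within_group_reordering_invariance(self):
        rng = np.random.default_rng(5)
        d, p = rng.random(20), rng.random(30)
        r1 = compare_groups(self._frame(d, p))
        r2 = compare_groups(self._frame(rng.permutation(d), rng.permutation(p)))
        assert r1.t_statistic == pytest.approx(r2.t_statistic, rel=1e-12)
        assert r1.u_statistic == r2.u_statistic  # rank-based: exactly equal
        assert r1.p_t == pytest.approx(r2.p_t, rel=1e-12)
        assert r1.p_u == pytest.approx(r2.p_u, rel=1e-12)

    def test_type_one_error_on_exchangeable_metrics(self):
        """Both tests hold their 5% level on exchangeable null metric vectors."""
        rng = np.random.default_rng(6)
        rej_t = rej_u = 0
        n_rep = 1000
        for _ in range(n_rep):
            frame = self._frame(rng.normal(0.3, 0.05, 60), rng.normal(0.3, 0.05, 120))
            res = compare_groups(frame)
            rej_t += res.p_t < 0.05
            rej_u += res.p_u < 0.05
        assert 0.035 <= rej_t / n_rep <= 0.065
        assert 0.035 <= rej_u / n_rep <= 0.065

    def test_directional_alternative(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.4, 0.05, 50)
        p = rng.normal(0.3, 0.05, 50)
        res = compare_groups(self._frame(d, p), alternative="greater")
        assert res.alternative == "greater"
        assert res.p_t < 0.01 and res.p_u < 0.01
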