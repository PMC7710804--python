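"""Cohort statistics: pooled t, Holm-Sidak, nodewise/global comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from curvnet.io import ValidationError
from curvnet.stats import (
    correlate_with_ci,
    global_comparison,
    holm_sidak,
    nodewise_comparison,
    pooled_t_test,
)

from oracles import brute_holm_sidak


class TestPooledT:
    def test_identical_samples(self):
        r = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0
        assert r.df == 4

    def test_shifted_samples_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        r = pooled_t_test(b, a)
        sp = 1.0  # pooled sd of two unit-variance samples of 3
        expected_t = 10.0 / (sp * np.sqrt(1 / 3 + 1 / 3))
        np.testing.assert_allclose(r.statistic, expected_t)
        assert r.p_value < 0.001
        assert r.mean_diff == 10.0

    def test_degenerate_samples_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            pooled_t_test([0.0, 0.0], [0.0, 0.0])

    def test_too_small_sample_error(self):
        with pytest.raises(ValidationError):
            pooled_t_test([1.0], [1.0, 2.0])

    def test_two_tailed_is_twice_smaller_one_tail(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.5, 1, 8), rng.normal(0, 1, 12)
        two = pooled_t_test(a, b, "two").p_value
        lo = pooled_t_test(a, b, "one_less").p_value
        hi = pooled_t_test(a, b, "one_greater").p_value
        np.testing.assert_allclose(two, 2 * min(lo, hi))


class TestHolmSidak:
    def test_single_test_reduces_to_plain_alpha(self):
        rej, adj = holm_sidak([0.03], alpha=0.05)
        assert rej[0] and adj[0] == 0.03

    def test_worked_example_all_rejected(self):
        rej, _ = holm_sidak([0.001, 0.02, 0.04], alpha=0.05)
        assert rej.all()

    def test_worked_example_none_rejected(self):
        # 0.02 > 1 - 0.95^(1/3) = 0.016952 stops the step-down immediately
        rej, _ = holm_sidak([0.02, 0.03, 0.5], alpha=0.05)
        assert not rej.any()

    def test_rejects_invalid_p(self):
        with pytest.raises(ValidationError):
            holm_sidak([0.5, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5))
    def test_matches_literal_step_down_definition(self, pvals):
        rej, adj = holm_sidak(pvals, alpha=0.05)
        brej, badj = brute_holm_sidak(pvals, alpha=0.05)
        np.testing.assert_array_equal(rej, brej)
        np.testing.assert_allclose(adj, badj, atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()

    def test_adjusted_p_invariant_to_permutation(self):
        rng = np.random.default_rng(5)
        p = rng.random(12)
        perm = rng.permutation(12)
        _, adj = holm_sidak(p)
        _, adj_p = holm_sidak(p[perm])
        np.testing.assert_allclose(adj_p, adj[perm])

    def test_adjusted_monotone_in_raw_rank(self):
        rng = np.random.default_rng(6)
        p = rng.random(30)
        _, adj = holm_sidak(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNodewise:
    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(1)
        n_nodes = 25
        A = rng.normal(0, 1, (12, n_nodes))  # "MSCI"
        B = rng.normal(0, 1, (8, n_nodes))   # "MSNI"
        A[:, 5] -= 4.0
        tab = nodewise_comparison(A, B, alpha=0.05)
        assert len(tab) == n_nodes
        assert tab.loc[5, "reject"]
        assert tab.loc[5, "direction"] == -1
        assert tab["reject"].sum() == 1
        assert (tab["adjusted_p"].dropna() >= tab["raw_p"].dropna() - 1e-12).all()

    def test_zero_variance_nodes_dropped_from_family(self):
        A = np.ones((5, 3))
        B = np.ones((4, 3))
        rng = np.random.default_rng(2)
        A[:, 1] = rng.normal(size=5)
        B[:, 1] = rng.normal(size=4)
        A[:, 2] = rng.normal(size=5)
        B[:, 2] = rng.normal(size=4)
        tab = nodewise_comparison(A, B)
        assert not tab.loc[0, "tested"]
        assert tab.loc[1:, "tested"].all()

    def test_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            nodewise_comparison(np.ones((1, 4)), np.ones((5, 4)))

    def test_permuted_labels_reject_at_nominal_rate(self):
        """Pooling and relabelling the cohorts keeps the family-wise
        rejection rate at (below) the nominal level."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            X = rng.normal(0, 1, (20, 40))
            perm = rng.permutation(20)
            tab = nodewise_comparison(X[perm[:12]], X[perm[12:]])
            hits += tab["reject"].any()
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestGlobal:
    def _tables(self, shift=0.0):
        rng = np.random.default_rng(4)
        cols = ["clustering_mean", "curvature", "density", "diameter",
                "global_efficiency", "characteristic_path_length",
                "small_worldness"]
        msci = pd.DataFrame(rng.normal(0, 1, (12, 7)), columns=cols)
        msni = pd.DataFrame(rng.normal(shift, 1, (8, 7)), columns=cols)
        return msci, msni

    DIRS = {"characteristic_path_length": "msci_greater",
            "diameter": "msci_greater"}

    def test_identical_cohorts_reject_nothing(self):
        msci, msni = self._tables()
        tab = global_comparison(msci, msni, directions=self.DIRS)
        assert len(tab) == 7
        assert not tab["reject"].any()

    def test_missing_direction_for_path_measures_errors(self):
        msci, msni = self._tables()
        with pytest.raises(ValidationError, match="direction"):
            global_comparison(msci, msni, directions={})

    def test_strong_global_shift_detected(self):
        msci, msni = self._tables(shift=3.0)
        tab = global_comparison(msci, msni, directions=self.DIRS)
        row = tab.set_index("measure_name").loc["curvature"]
        assert row["reject"]

    def test_zero_variance_measure_dropped_not_fatal(self):
        msci, msni = self._tables()
        msci["density"] = 1.0
        msni["density"] = 1.0
        tab = global_comparison(msci, msni, directions=self.DIRS)
        row = tab.set_index("measure_name").loc["density"]
        assert not row["tested"] and not row["reject"]


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        r = correlate_with_ci(x, x)
        np.testing.assert_allclose(r.pearson_r, 1.0)
        r = correlate_with_ci(x, -x)
        np.testing.assert_allclose(r.pearson_r, -1.0)
        assert r.n == 10

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError, match="variance"):
            correlate_with_ci(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_error(self):
        with pytest.raises(ValidationError):
            correlate_with_ci([1.0, 2.0], [0.1, 0.2])

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = correlate_with_ci(x, y)
        from scipy import stats as sps
        t = res.pearson_r * np.sqrt((res.n - 2) / (1 - res.pearson_r ** 2))
        np.testing.assert_allclose(res.p_value,
                                   2 * sps.t.sf(abs(t), res.n - 2), rtol=1e-10)
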