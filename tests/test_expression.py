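"""Expression aggregation, TMM normalization, adaptive testing, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse, stats

from evscope.expression import (ExpressionSet, aggregate, bh_adjust,
                                differential_test, mann_whitney, select_test,
                                tmm_norm_factors, tmm_normalize)
from evscope.matrix import SingleEVMatrix


def _mat(sample, rows, proteins):
    return SingleEVMatrix(sample, [f"ev{i}" for i in range(len(rows))],
                          proteins, sparse.csr_matrix(np.array(rows)))


class TestAggregate:
    def test_column_sums(self):
        proteins = ["CDCP1", "EPCAM"]
        m1 = _mat("s1", [[2, 0]], proteins)
        m2 = _mat("s2", [[1, 1], [3, 0]], proteins)
        groups = pd.Series({"s1": "A", "s2": "B"})
        expr = aggregate({"s1": m1, "s2": m2}, groups)
        assert expr.counts.loc["CDCP1", "s1"] == 2
        assert expr.counts.loc["CDCP1", "s2"] == 4
        assert expr.counts.loc["EPCAM", "s2"] == 1

    def test_panel_mismatch_rejected(self):
        m1 = _mat("s1", [[1]], ["A"])
        m2 = _mat("s2", [[1]], ["B"])
        with pytest.raises(ValueError):
            aggregate({"s1": m1, "s2": m2}, pd.Series({"s1": "x", "s2": "y"}))

    def test_matches_generator_totals(self, clean_truth):
        expr = aggregate(clean_truth.matrices, clean_truth.sample_groups)
        for sid, mat in clean_truth.matrices.items():
            expected = np.asarray(mat.counts.sum(axis=0)).ravel()
            np.testing.assert_array_equal(expr.counts[sid].to_numpy(),
                                          expected)


class TestTMM:
    def test_identical_samples_factor_one(self):
        col = np.arange(1, 51)
        counts = pd.DataFrame({"a": col, "b": col})
        np.testing.assert_allclose(tmm_norm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed(self):
        """B = 2 x A elementwise: all M-values are zero, factors are 1."""
        rng = np.random.default_rng(1)
        a = rng.poisson(30, size=100) + 1
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(tmm_norm_factors(counts), 1.0)

    def test_matches_edger_reference(self):
        """Frozen factors computed by edgeR::calcNormFactors on this exact
        fixture."""
        rng = np.random.default_rng(42)
        mu = rng.gamma(2.0, 50.0, size=113)
        depth = np.array([0.5, 0.8, 1.0, 1.3, 2.0, 3.1])
        counts = rng.negative_binomial(
            5, 5 / (5 + mu[:, None] * depth[None, :]))
        expected = [1.0165645689, 0.9959750118, 1.0209511035,
                    0.9666519160, 0.9985741079, 1.0022157620]
        np.testing.assert_allclose(
            tmm_norm_factors(pd.DataFrame(counts)).to_numpy(), expected,
            atol=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(20, size=(80, 7)) + 1)
        f = tmm_norm_factors(counts)
        assert abs(np.log(f).mean()) < 1e-12

    def test_invariant_to_depth_scaling(self):
        """Depth-scaling a sample leaves factors essentially unchanged
        (exactly so up to the library-size-dependent precision weights)."""
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.poisson(50, size=(60, 4)) + 1)
        scaled = counts.copy()
        scaled[2] = counts[2] * 5
        f1 = tmm_norm_factors(counts)
        f2 = tmm_norm_factors(scaled)
        np.testing.assert_allclose(f1, f2, rtol=5e-3)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(counts)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_definition(self, p_list):
        """Independent step-up: q_i = min_{j: p_j >= p_i} min(1, m p_j / r_j)
        with r_j the 1-based ascending rank."""
        p = np.array(p_list)
        m = p.size
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            brute[order[i]] = min(
                min(1.0, m * sorted_p[j] / (j + 1)) for j in range(i, m))
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)


class TestMannWhitney:
    def test_exact_matches_scipy_without_ties(self):
        x = [1.2, 3.4, 2.2, 5.1]
        y = [0.5, 2.9, 4.0, 0.1]
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        """Brute-force two-sided exact p over all rank splits (doubled
        smaller tail), independently coded here."""
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 4.0])
        u, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1 = len(x)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n1):
            us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        us = np.array(us)
        expected = min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSelectTest:
    @pytest.mark.parametrize("sw1,sw2,fp,expected", [
        (0.5, 0.5, 0.5, "student_t"),
        (0.5, 0.5, 0.01, "welch_t"),
        (0.01, 0.5, 0.5, "mann_whitney"),
        (0.5, 0.01, 0.01, "mann_whitney"),
        (0.04, 0.04, 0.9, "mann_whitney"),
        (0.05, 0.05, 0.05, "student_t"),  # gates are strict inequalities
    ])
    def test_truth_table(self, sw1, sw2, fp, expected):
        assert select_test(sw1, sw2, fp) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_tree_is_total_and_consistent(self, a, b, c):
        out = select_test(a, b, c)
        if a < 0.05 or b < 0.05:
            assert out == "mann_whitney"
        elif c < 0.05:
            assert out == "welch_t"
        else:
            assert out == "student_t"


def _expr_from_arrays(case, ctrl, protein_names=None):
    n_p = case.shape[0]
    names = protein_names or [f"P{i}" for i in range(n_p)]
    samples = [f"c{i}" for i in range(case.shape[1])] + \
        [f"k{i}" for i in range(ctrl.shape[1])]
    counts = pd.DataFrame(np.hstack([case, ctrl]), index=names,
                          columns=samples)
    groups = pd.Series(["case"] * case.shape[1] + ["ctrl"] * ctrl.shape[1],
                       index=samples)
    return ExpressionSet(counts, groups)


class TestDifferentialTest:
    def test_planted_shift_detected_up(self):
        rng = np.random.default_rng(3)
        base = rng.gamma(5, 20, size=(20, 1))
        case = rng.poisson(np.tile(base, (1, 8)))
        ctrl = rng.poisson(np.tile(base, (1, 18)))
        case[0] *= 10  # planted 10-fold CDCP1 shift in the case group
        expr = _expr_from_arrays(case.astype(float), ctrl.astype(float),
                                 ["CDCP1"] + [f"P{i}" for i in range(1, 20)])
        res = differential_test(expr, "case", use_normalized=False)
        assert res.loc["CDCP1", "q_value"] < 0.05
        assert res.loc["CDCP1", "direction"] == "up"

    def test_null_labels_mostly_nonsignificant(self):
        rng = np.random.default_rng(4)
        pooled = rng.poisson(50, size=(20, 26)).astype(float)
        expr = _expr_from_arrays(pooled[:, :8], pooled[:, 8:])
        res = differential_test(expr, "case", use_normalized=False)
        assert (res.q_value < 0.05).sum() == 0

    def test_constant_protein_flagged_and_excluded(self):
        rng = np.random.default_rng(5)
        case = rng.poisson(30, (3, 5)).astype(float)
        ctrl = rng.poisson(30, (3, 5)).astype(float)
        case[1] = ctrl[1] = 7.0
        expr = _expr_from_arrays(case, ctrl)
        res = differential_test(expr, "case", use_normalized=False)
        assert res.loc["P1", "test_used"] == "undefined"
        assert np.isnan(res.loc["P1", "q_value"])
        # BH family size excludes the undefined protein
        valid = res[res.test_used != "undefined"]
        np.testing.assert_allclose(
            valid.q_value, bh_adjust(valid.p_value.to_numpy()))

    def test_small_groups_rejected(self):
        expr = _expr_from_arrays(np.ones((3, 2)), np.ones((3, 5)))
        with pytest.raises(ValueError, match="n >= 3"):
            differential_test(expr, "case", use_normalized=False)

    def test_normalized_pipeline_runs(self, clean_truth):
        expr = aggregate(clean_truth.matrices, clean_truth.sample_groups)
        tmm_normalize(expr)
        res = differential_test(expr, "OVCA")
        # the planted tumor subcluster drives CDCP1 up in OVCA
        assert res.loc["CDCP1", "direction"] == "up"
        assert set(res.test_used.unique()) <= {
            "student_t", "welch_t", "mann_whitney", "undefined"}
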