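"""Differential expression: fold changes, Welch test, BH-FDR, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mevrank.deg import bh_adjust, compute_logfc, run_contrasts, two_sample_test
from mevrank.errors import InsufficientSamplesError, MissingConditionError, ValidationError

from conftest import make_expression


def two_group_matrix(a_vals, b_vals, gene="g1", scale="log2"):
    values = np.array([list(a_vals) + list(b_vals)], dtype=float)
    conds = ["M1"] * len(a_vals) + ["M2"] * len(b_vals)
    return make_expression(values, [gene], conds, scale=scale)


class TestLogFC:
    def test_worked_ratio(self):
        # linear means 8 (M1) vs 2 (M2) -> log2(8/2) = 2
        expr = two_group_matrix([8, 8, 8], [2, 2, 2], scale="linear")
        assert compute_logfc(expr, "M1", "M2")["g1"] == pytest.approx(2.0, abs=1e-6)

    def test_equal_means_zero(self):
        expr = two_group_matrix([5, 5, 5], [5, 5, 5], scale="linear")
        assert compute_logfc(expr, "M1", "M2")["g1"] == pytest.approx(0.0)

    def test_planted_up_gene_positive(self, zero_noise_expression):
        expr, truth = zero_noise_expression
        logfc = compute_logfc(expr, "M1", "M2")
        assert (logfc[list(truth.planted_up)] > 0).all()
        assert (logfc[list(truth.planted_down)] < 0).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1, 12, size=(5, 4))
        expr = make_expression(values, [f"g{i}" for i in range(5)], ["M1", "M1", "M2", "M2"])
        fwd = compute_logfc(expr, "M1", "M2")
        rev = compute_logfc(expr, "M2", "M1")
        assert np.allclose(fwd, -rev)

    def test_missing_condition_named_error(self):
        expr = two_group_matrix([1, 2], [3, 4])
        with pytest.raises(MissingConditionError):
            compute_logfc(expr, "M1", "M0")


class TestWelch:
    def test_matches_textbook_computation(self):
        # A=(1,2,3) vs B=(4,5,6): t = -3/sqrt(2/3), df = 4 by
        # Welch-Satterthwaite, p from the t(4) tail (hand-derived oracle)
        expr = two_group_matrix([1, 2, 3], [4, 5, 6])
        res = two_sample_test(expr, "M1", "M2")
        assert res["t"]["g1"] == pytest.approx(-3.6742346141747673, rel=1e-12)
        assert res["p"]["g1"] == pytest.approx(0.021311641128756713, rel=1e-9)

    def test_identical_groups(self):
        expr = two_group_matrix([2, 2, 2], [2, 2, 2])
        res = two_sample_test(expr, "M1", "M2")
        assert res["t"]["g1"] == 0.0
        assert res["p"]["g1"] == 1.0

    def test_flat_unequal_groups_flagged(self):
        expr = two_group_matrix([3, 3, 3], [1, 1, 1])
        res = two_sample_test(expr, "M1", "M2")
        assert res["degenerate"]["g1"]
        assert 0 < res["p"]["g1"] < 1e-300
        assert np.isposinf(res["t"]["g1"])

    def test_swap_negates_t_preserves_p(self):
        expr = two_group_matrix([1.0, 2.5, 3.1], [4.2, 4.9, 6.6])
        fwd = two_sample_test(expr, "M1", "M2")
        rev = two_sample_test(expr, "M2", "M1")
        assert fwd["t"]["g1"] == pytest.approx(-rev["t"]["g1"])
        assert fwd["p"]["g1"] == pytest.approx(rev["p"]["g1"])

    def test_single_sample_group_rejected(self):
        expr = two_group_matrix([1, 2], [3, 4])
        values = expr.values[["s0", "s1", "s2"]]
        import pandas as pd

        from mevrank.expression import ExpressionMatrix

        with pytest.raises(ValidationError):
            # 1-sample condition is already rejected by the container
            ExpressionMatrix(values, pd.Series(["M1", "M1", "M2"], index=values.columns))


def brute_force_bh(p):
    """Step-up definition evaluated literally: q_(i) = min_{j>=i} m p_(j)/j,
    capped at 1 and floored at p_(i) (the formula implies q >= p since
    m/j >= 1; the explicit floor guards the float rounding of m*p/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = []
    for i in range(m):
        q = min(m * ranked[j] / (j + 1) for j in range(i, m))
        q_sorted.append(max(min(q, 1.0), ranked[i]))
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_vectors(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_brute_force_and_is_monotone(self, p):
        q = bh_adjust(p)
        assert np.array_equal(q, brute_force_bh(p))
        assert (q >= np.asarray(p)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= 0).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_ref)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)


class TestContrasts:
    def test_zero_noise_recovers_planted_set_exactly(self, zero_noise_expression):
        expr, truth = zero_noise_expression
        result = run_contrasts(expr, alpha=0.05)
        assert result.intersection == frozenset(truth.planted_up) | frozenset(truth.planted_down)

    def test_significance_flag_tracks_alpha(self, zero_noise_expression):
        expr, _ = zero_noise_expression
        for alpha in (0.01, 0.05, 0.2):
            result = run_contrasts(expr, alpha=alpha)
            for table in result.tables.values():
                assert ((table["p_adj"] < alpha) == table["significant"]).all()

    def test_logfc_oriented_positive_up_in_m1(self, zero_noise_expression):
        expr, truth = zero_noise_expression
        result = run_contrasts(expr)
        for table in result.tables.values():
            assert (table.loc[list(truth.planted_up), "logFC"] > 0).all()

    def test_false_positive_control(self):
        # null genes enter the intersection at well under alpha * m
        from mevrank.synthetic import SimulationParams, generate_expression

        fps = []
        for seed in range(20):
            params = SimulationParams.default(seed=seed)
            expr, truth = generate_expression(params)
            result = run_contrasts(expr)
            planted = set(truth.planted_up) | set(truth.planted_down)
            fps.append(len(result.intersection - planted))
        assert np.mean(fps) <= 0.05 * 500

    def test_direction_concordance_filter(self):
        # one gene up in M1-vs-M0 but down in M1-vs-M2: concordance drops it
        rng = np.random.default_rng(0)
        base = rng.normal(6, 0.01, size=(1, 9))
        base[0, 3:6] += 3.0   # M1 high vs M0
        base[0, 6:9] += 6.0   # M2 even higher -> discordant signs
        expr = make_expression(base, ["gx"], ["M0"] * 3 + ["M1"] * 3 + ["M2"] * 3)
        strict = run_contrasts(expr, direction_concordance=True)
        loose = run_contrasts(expr, direction_concordance=False)
        assert "gx" not in strict.intersection
        assert "gx" in loose.intersection
        assert "gx" in strict.discordant
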