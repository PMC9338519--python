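"""Unit and property tests for the Binary cFDR core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bincfdr.core import (
    P_FLOOR,
    EmpiricalCdf,
    RejectionRegion,
    SummaryTable,
    bh_adjust,
    binary_cfdr,
    cfdr_ratio,
    estimate_null_covariate_rate,
    fit_stratum_model,
    iterate_cfdr,
    monotone_cfdr_ratio,
    solve_matched_threshold,
    v_value,
)

from conftest import make_table


class TestSummaryTable:
    def test_rejects_out_of_range_p_naming_rows(self):
        with pytest.raises(ValueError, match=r"column 'p'.*rows 1"):
            SummaryTable(p=[0.5, 0.0, 0.2], q=[0, 1, 0], group=[1, 1, 2])

    def test_rejects_non_binary_q(self):
        with pytest.raises(ValueError, match=r"column 'q'"):
            SummaryTable(p=[0.5, 0.1], q=[0, 2], group=[1, 2])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            SummaryTable(p=[0.5, 0.1], q=[0], group=[1, 2])

    def test_p_clamp_via_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"snp": ["a"], "p": [0.0], "q": [1], "group": [1]})
        with pytest.raises(ValueError):
            SummaryTable.from_dataframe(df)
        t = SummaryTable.from_dataframe(df, allow_p_clamp=True)
        assert t.p[0] == P_FLOOR


class TestNullCovariateRate:
    def test_constant_q(self):
        t0 = SummaryTable(p=[0.2, 0.6, 0.9], q=[0, 0, 0], group=[1, 1, 2])
        t1 = SummaryTable(p=[0.2, 0.6, 0.9], q=[1, 1, 1], group=[1, 1, 2])
        assert estimate_null_covariate_rate(t0) == 0.0
        assert estimate_null_covariate_rate(t1) == 1.0

    def test_only_null_region_counts(self):
        # four SNPs with p > 0.5, two of them covariate-positive
        t = SummaryTable(
            p=[0.6, 0.7, 0.8, 0.9, 0.1], q=[0, 1, 0, 1, 1], group=[1, 1, 1, 2, 2]
        )
        assert estimate_null_covariate_rate(t) == 0.5

    def test_fallback_when_no_large_p(self):
        t = SummaryTable(p=[0.1, 0.2, 0.3, 0.4], q=[1, 0, 0, 0], group=[1, 1, 2, 2])
        assert estimate_null_covariate_rate(t) == 0.25

    def test_empty_fold_errors(self):
        t = SummaryTable(p=[0.5], q=[0], group=[1])
        with pytest.raises(ValueError, match="empty"):
            estimate_null_covariate_rate(t.subset(np.array([False])))


class TestEmpiricalCdf:
    def test_continuity_corrected_values(self):
        e = EmpiricalCdf(np.array([0.1, 0.5, 0.9]))
        assert e(0.5) == pytest.approx((2 + 1) / (3 + 1))
        assert e(1.0) == 1.0
        assert e(1e-9) == pytest.approx(1 / 4)  # positive below the smallest point

    def test_concave_majorant_dominates_and_is_monotone(self):
        rng = np.random.default_rng(0)
        e = EmpiricalCdf(rng.uniform(size=200))
        # dominates the step estimate from the first data point onwards (below
        # it the hull runs to the origin while the corrected step stays at
        # 1/(m+1)); is nondecreasing and anchored at (1, 1)
        x = np.linspace(e.knots[0], 1, 500)
        assert np.all(e.concave(x) >= e(x) - 1e-12)
        assert np.all(np.diff(e.concave(x)) >= -1e-15)
        assert e.concave(1.0) == 1.0
        assert e.concave(1e-9) > 0.0


class TestCfdrRatio:
    def test_hand_value(self, toy_model):
        # 0.5 * 0.5 / (0.75 * 0.5)
        assert cfdr_ratio(0.5, 0, toy_model) == pytest.approx(2 / 3)

    def test_boundary_identity_at_one(self, toy_model):
        # ecdf(1) = 1, so the ratio collapses to null_rate / marginal
        assert cfdr_ratio(1.0, 0, toy_model) == pytest.approx(
            toy_model.null_rate(0) / toy_model.marginal(0)
        )
        assert cfdr_ratio(1.0, 1, toy_model) == pytest.approx(
            toy_model.null_q / toy_model.marginal_q
        )

    def test_near_one_under_independence(self):
        rng = np.random.default_rng(11)
        model = fit_stratum_model(make_table(rng, 100_000, q_rate=0.3, n_groups=2))
        grid = np.linspace(0.01, 1.0, 200)
        for s in (0, 1):
            assert np.max(np.abs(cfdr_ratio(grid, s, model) - 1.0)) < 0.1
            assert np.max(np.abs(monotone_cfdr_ratio(grid, s, model) - 1.0)) < 0.1

    def test_rejects_invalid_p(self, toy_model):
        with pytest.raises(ValueError):
            cfdr_ratio(0.0, 0, toy_model)

    def test_empty_stratum_errors(self):
        t = SummaryTable(p=[0.2, 0.4, 0.9], q=[0, 0, 0], group=[1, 1, 2])
        model = fit_stratum_model(t)
        with pytest.raises(ValueError, match="degenerate"):
            cfdr_ratio(0.5, 1, model)


class TestMatchedThreshold:
    def test_symmetric_strata_fixed_point(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=200)
        t = SummaryTable(
            p=np.concatenate([vals, vals]),
            q=np.repeat([0, 1], 200),
            group=np.zeros(400, int),
        )
        model = fit_stratum_model(t)
        model.null_q = model.marginal_q  # identical ratio curves in both strata
        for p_i in np.linspace(0.02, 0.99, 25):
            region = solve_matched_threshold(float(p_i), 0, model)
            assert region.p0 == p_i
            assert region.p1 == pytest.approx(p_i, abs=1e-9)

    def test_clamp_to_one_when_target_exceeds_opposite_curve(self, toy_model):
        # null_q = 0.9 makes the stratum-1 ratio at p=1 (= 1.8) exceed the
        # whole stratum-0 curve (max 0.2), so the matched p0 clamps to 1.
        toy_model.null_q = 0.9
        region = solve_matched_threshold(1.0, 1, toy_model)
        assert region.p0 == 1.0

    def test_clamp_to_zero_below_achievable_ratio(self, toy_model):
        toy_model.null_q = 1e-12  # target for q=1 becomes vanishingly small
        region = solve_matched_threshold(1e-6, 1, toy_model)
        assert region.p0 == 0.0

    def test_degenerate_stratum_returns_identity_region(self):
        t = SummaryTable(p=[0.2, 0.4, 0.9], q=[0, 0, 0], group=[1, 1, 2])
        model = fit_stratum_model(t)
        region = solve_matched_threshold(0.3, 0, model)
        assert (region.p0, region.p1) == (0.3, 0.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = SummaryTable(
            p=rng.uniform(size=50) ** 2,
            q=(rng.random(50) < 0.4).astype(int),
            group=np.zeros(50, int),
        )
        model = fit_stratum_model(t)
        grid = np.linspace(1e-12, 1.0, 10_000)
        for _ in range(5):
            p_i = float(rng.uniform(1e-6, 1.0))
            q_i = int(rng.random() < 0.5)
            region = solve_matched_threshold(p_i, q_i, model)
            target = monotone_cfdr_ratio(p_i, q_i, model)
            r = monotone_cfdr_ratio(grid, 1 - q_i, model)
            ok = np.flatnonzero(r <= target)
            expected = 0.0 if ok.size == 0 else grid[ok[-1]]
            got = region.p1 if q_i == 0 else region.p0
            assert abs(got - expected) <= 1.5e-4  # within one grid step


class TestVValue:
    def test_examples(self):
        assert v_value(RejectionRegion(0.01, 0.1), 0.2) == pytest.approx(0.028)
        assert v_value(RejectionRegion(0.3, 0.3), 0.77) == pytest.approx(0.3)
        assert v_value(RejectionRegion(0.25, 0.9), 0.0) == 0.25

    def test_floor(self):
        assert v_value(RejectionRegion(0.0, 0.0), 0.5) == P_FLOOR

    @settings(derandomize=True, max_examples=100)
    @given(
        p0=st.floats(0, 1),
        p1=st.floats(0, 1),
        q0=st.floats(0, 1),
    )
    def test_convex_combination_bounds(self, p0, p1, q0):
        v = v_value(RejectionRegion(p0, p1), q0)
        assert max(P_FLOOR, min(p0, p1)) - 1e-12 <= v <= max(p0, p1, P_FLOOR) + 1e-12


class TestBinaryCfdr:
    def test_constant_covariate_identity_is_exact(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=5000)
        group = np.arange(5000) % 4
        for qval in (0, 1):
            t = SummaryTable(p=p, q=np.full(5000, qval), group=group)
            res = binary_cfdr(t)
            assert np.array_equal(res.v, p)

    def test_single_group_errors(self):
        t = SummaryTable(p=[0.1, 0.2], q=[0, 1], group=[1, 1])
        with pytest.raises(ValueError, match="2 distinct groups"):
            binary_cfdr(t)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        t = make_table(rng, 2000)
        assert np.array_equal(binary_cfdr(t).v, binary_cfdr(t).v)

    def test_agrees_with_scalar_solver_and_conserves_null_mass(self):
        rng = np.random.default_rng(9)
        t = make_table(rng, 600, q_rate=0.3, n_groups=3)
        res = binary_cfdr(t)
        for i in rng.choice(600, size=60, replace=False):
            model = fit_stratum_model(t.subset(t.group != t.group[i]))
            region = solve_matched_threshold(float(t.p[i]), int(t.q[i]), model)
            expected = region.p0 * (1 - model.null_q) + region.p1 * model.null_q
            assert res.v[i] == pytest.approx(expected, rel=1e-12)

    def test_v_nondecreasing_in_p_within_group_and_stratum(self):
        rng = np.random.default_rng(10)
        t = make_table(rng, 4000, q_rate=0.2, n_groups=4)
        res = binary_cfdr(t)
        for g in range(4):
            for s in (0, 1):
                idx = np.flatnonzero((t.group == g) & (t.q == s))
                order = idx[np.argsort(t.p[idx])]
                assert np.all(np.diff(res.v[order]) >= -1e-12)

    def test_fdr_dominates_v(self):
        rng = np.random.default_rng(12)
        res = binary_cfdr(make_table(rng, 1000))
        assert np.all(res.fdr >= res.v - 1e-15)


class TestIterateCfdr:
    def test_single_covariate_equals_one_shot(self):
        rng = np.random.default_rng(21)
        t = make_table(rng, 1000)
        trace = iterate_cfdr(t, [t.q])
        assert len(trace) == 1
        assert np.array_equal(trace[0].v, binary_cfdr(t).v)

    def test_all_zero_covariates_return_input_p(self):
        rng = np.random.default_rng(22)
        t = make_table(rng, 500)
        zeros = np.zeros(500, int)
        trace = iterate_cfdr(t, [zeros, zeros, zeros])
        assert np.array_equal(trace[-1].v, t.p)

    def test_chains_v_as_next_p(self):
        rng = np.random.default_rng(23)
        t = make_table(rng, 800)
        q2 = (rng.random(800) < 0.1).astype(int)
        trace = iterate_cfdr(t, [t.q, q2])
        second = binary_cfdr(
            SummaryTable(p=trace[0].v, q=q2, group=t.group), iteration=2
        )
        assert np.array_equal(trace[1].v, second.v)

    def test_length_mismatch_errors(self):
        rng = np.random.default_rng(24)
        t = make_table(rng, 100)
        with pytest.raises(ValueError, match="length"):
            iterate_cfdr(t, [np.zeros(99, int)])


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_constant(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1e-300, 1.0), min_size=1, max_size=30)
    )
    def test_dominates_input_and_capped(self, vals):
        adj = bh_adjust(vals)
        assert np.all(adj >= np.asarray(vals) - 1e-15)
        assert np.all(adj <= 1.0)
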