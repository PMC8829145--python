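"""Accuracy criteria: relative bias, MSE, coverage, convergence, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regmixsim as rm
from regmixsim.evaluate import (
    ReplicationRecord,
    ci_coverage,
    parameter_names,
    relative_bias,
    true_parameter_values,
)


class TestRelativeBias:
    def test_zero_when_exact(self):
        assert relative_bias([0.7, 0.7, 0.7], 0.7) == pytest.approx(0.0, abs=1e-12)

    def test_absent_for_zero_truth(self):
        assert relative_bias([0.1, -0.2], 0.0) is None

    def test_small_bias_not_flagged(self):
        # mean estimate 0.6264 against truth 0.626
        rb = relative_bias([0.6264], 0.626)
        assert rb == pytest.approx(0.000639, abs=1e-6)
        assert abs(rb) <= 0.1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            relative_bias([], 0.5)


class TestMse:
    def test_zero_when_exact(self):
        assert rm.mse([0.7, 0.7], 0.7) == 0.0

    def test_hand_arithmetic(self):
        assert rm.mse([0.6, 0.8], 0.7) == pytest.approx(0.01)

    def test_approaches_variance_for_unbiased_estimates(self):
        """Oracle: for estimates ~ N(theta, tau^2), MSE -> tau^2."""
        rng = np.random.default_rng(3)
        tau = 0.3
        draws = rng.normal(0.7, tau, size=200_000)
        assert rm.mse(draws, 0.7) == pytest.approx(tau**2, rel=0.02)


class TestCoverage:
    def test_all_covered(self):
        assert ci_coverage([0.7, 0.71], [0.1, 0.1], 0.7) == 1.0

    def test_none_covered_with_tiny_se(self):
        assert ci_coverage([0.9, 0.5], [1e-12, 1e-12], 0.7) == 0.0

    def test_calibrated_in_correct_normal_model(self):
        """Oracle: exact normal intervals cover at the nominal rate."""
        rng = np.random.default_rng(11)
        reps, se = 5000, 0.05
        est = rng.normal(0.7, se, size=reps)
        cov = ci_coverage(est, np.full(reps, se), 0.7)
        assert cov == pytest.approx(0.95, abs=3 * np.sqrt(0.95 * 0.05 / reps))

    def test_monotone_in_interval_width(self):
        rng = np.random.default_rng(5)
        est = rng.normal(0.7, 0.1, size=200)
        ses = np.full(200, 0.05)
        narrow = ci_coverage(est, ses, 0.7, z=1.0)
        wide = ci_coverage(est, ses, 0.7, z=3.0)
        assert narrow <= wide <= 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ci_coverage([0.7], [0.0], 0.7)


def _record(cond, rep, variant, converged, value=None, se=0.05):
    if not converged:
        return ReplicationRecord(cond.condition_id, rep, variant, converged=False)
    names = parameter_names(cond.n_predictors)
    truths = true_parameter_values(cond)
    est = {n: (truths[n] if value is None else value) for n in names}
    ses = {n: se for n in names}
    return ReplicationRecord(
        cond.condition_id, rep, variant, converged=True, estimates=est, ses=ses
    )


@pytest.fixture
def cond():
    return rm.make_condition("single_no_intdiff", "large", 300)


class TestConvergenceRate:
    def test_all_converged(self, cond):
        recs = [_record(cond, r, "free", True) for r in range(100)]
        assert rm.convergence_rate(recs) == 1.0

    def test_partial(self, cond):
        recs = [_record(cond, r, "free", r >= 3) for r in range(100)]
        assert rm.convergence_rate(recs) == pytest.approx(0.97)

    def test_none_converged(self, cond):
        recs = [_record(cond, r, "free", False) for r in range(10)]
        assert rm.convergence_rate(recs) == 0.0

    def test_mixed_variants_rejected(self, cond):
        recs = [_record(cond, 0, "free", True), _record(cond, 0, "constrained", True)]
        with pytest.raises(ValueError):
            rm.convergence_rate(recs)
        with pytest.raises(ValueError):
            rm.convergence_rate([])


class TestSummarize:
    def test_exact_estimates_give_zero_error_full_coverage(self, cond):
        recs = [_record(cond, r, v, True, se=10.0) for r in range(5) for v in ("free", "constrained")]
        summaries = rm.summarize_condition(recs, cond)
        assert {s.variant for s in summaries} == {"free", "constrained"}
        for s in summaries:
            assert s.convergence_rate == 1.0
            for ps in s.parameters.values():
                assert ps.mse == 0.0
                assert ps.coverage == 1.0
                assert ps.relative_bias in (0.0, None)
                # intercepts are 0 here, so their relative bias is absent
                if "intercept" in ps.parameter:
                    assert ps.relative_bias is None

    def test_matches_hand_computed_metrics(self, cond):
        vals = [0.6, 0.8, 0.7]
        recs = [_record(cond, r, "free", True, value=v, se=0.2) for r, v in enumerate(vals)]
        s = rm.summarize_condition(recs, cond)[0]
        ps = s.parameters["class1_slope_x1"]  # truth 0.7
        assert ps.mean_estimate == pytest.approx(0.7)
        assert ps.relative_bias == pytest.approx(0.0, abs=1e-12)
        assert ps.mse == pytest.approx((0.01 + 0.01 + 0.0) / 3)
        # independent recomputation through the individual operations
        assert ps.mse == pytest.approx(rm.mse(vals, 0.7))
        assert ps.coverage == pytest.approx(ci_coverage(vals, [0.2] * 3, 0.7))

    def test_aggregates_converged_only(self, cond):
        recs = [_record(cond, 0, "free", True, value=0.7)] + [
            _record(cond, r, "free", False) for r in (1, 2, 3)
        ]
        s = rm.summarize_condition(recs, cond)[0]
        assert s.n_converged == 1
        assert s.convergence_rate == 0.25
        assert s.parameters["class1_slope_x1"].mean_estimate == pytest.approx(0.7)

    def test_no_converged_replications(self, cond):
        recs = [_record(cond, r, "free", False) for r in range(4)]
        s = rm.summarize_condition(recs, cond)[0]
        assert s.convergence_rate == 0.0
        assert s.parameters == {}

    @settings(derandomize=True, max_examples=25)
    @given(perm_seed=st.integers(0, 10_000))
    def test_metrics_invariant_to_record_order(self, perm_seed):
        cond = rm.make_condition("single_no_intdiff", "large", 300)
        rng = np.random.default_rng(42)
        vals = rng.normal(0.7, 0.1, size=8)
        recs = [_record(cond, r, "free", True, value=v) for r, v in enumerate(vals)]
        shuffled = list(recs)
        np.random.default_rng(perm_seed).shuffle(shuffled)
        a = rm.summarize_condition(recs, cond)[0]
        b = rm.summarize_condition(shuffled, cond)[0]
        for name in a.parameters:
            assert a.parameters[name].mse == pytest.approx(b.parameters[name].mse)
            assert a.parameters[name].coverage == b.parameters[name].coverage


def test_tidy_and_wide_tables(cond):
    recs = [_record(cond, r, v, True) for r in range(3) for v in ("free", "constrained")]
    summaries = rm.summarize_condition(recs, cond)
    tidy = rm.summaries_to_tidy(summaries)
    assert len(tidy) == 2 * len(parameter_names(1))
    assert set(tidy["variant"]) == {"free", "constrained"}
    wide = rm.summaries_to_wide(summaries)
    assert {"free", "constrained"} <= set(wide.columns)
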