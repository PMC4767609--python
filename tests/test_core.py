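import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hierfdr import (
    CriticalValues,
    aorc_critical_values,
    linear_critical_values,
    lsu_test,
    sud_test,
)
from conftest import sud_oracle


class TestCriticalValues:
    def test_linear_values(self):
        cv = linear_critical_values(5, 0.05)
        np.testing.assert_allclose(cv.thresholds, [0.01, 0.02, 0.03, 0.04, 0.05])
        assert cv.order == 5
        assert linear_critical_values(1, 0.05).thresholds[0] == pytest.approx(0.05)
        assert linear_critical_values(2500, 0.05).thresholds[-1] == pytest.approx(0.05)

    def test_aorc_values(self):
        cv = aorc_critical_values(5, 0.05)
        np.testing.assert_allclose(
            cv.thresholds, [0.012346, 0.032258, 0.069767, 0.166667, 1.0], rtol=1e-4)
        assert aorc_critical_values(100, 0.05).thresholds[9] == pytest.approx(0.5 / 90.5)
        # last critical value is exactly 1 and the sequence strictly increases
        for m in (1, 2, 7, 100):
            t = aorc_critical_values(m, 0.3).thresholds
            assert t[-1] == 1.0
            assert np.all(np.diff(t) > 0) or m == 1

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            linear_critical_values(5, alpha)
        with pytest.raises(ValueError):
            aorc_critical_values(5, alpha)

    def test_invalid_m_and_order(self):
        with pytest.raises(ValueError):
            linear_critical_values(0, 0.05)
        with pytest.raises(ValueError):
            CriticalValues(np.array([0.05, 0.01]), 1)  # decreasing
        with pytest.raises(ValueError):
            CriticalValues(np.array([0.01, 0.05]), 3)  # order out of range


class TestSUD:
    def test_step_up_branch_stops_at_first_gap(self):
        crit = aorc_critical_values(5, 0.05, order=2)
        res = sud_test([0.010, 0.015, 0.02, 0.9, 0.95], crit)
        assert res.threshold_index == 3
        assert res.threshold_value == pytest.approx(0.069767, rel=1e-4)
        assert res.num_rejections == 3

    def test_step_down_branch(self):
        crit = aorc_critical_values(5, 0.05, order=2)
        res = sud_test([0.010, 0.040, 0.5, 0.6, 0.7], crit)
        assert res.threshold_index == 1
        assert res.num_rejections == 1

    def test_nothing_passes(self):
        crit = linear_critical_values(5, 0.05, order=3)
        res = sud_test([1.0] * 5, crit)
        assert res.num_rejections == 0
        assert res.threshold_index is None
        assert res.threshold_value is None

    def test_degenerate_aorc_step_up_rejects_everything(self):
        # a_{m:m} = 1, so a pure step-up AORC run rejects all once any p <= 1
        crit = aorc_critical_values(4, 0.05, order=4)
        res = sud_test([0.99, 0.5, 0.7, 1.0], crit)
        assert res.num_rejections == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sud_test([0.1, 0.2], linear_critical_values(3, 0.05))

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        crit_alpha = 0.2
        for _ in range(2000):
            m = int(rng.integers(1, 9))
            # coarse grid keeps ties frequent
            p = rng.integers(0, 11, size=m) / 10.0
            lam = int(rng.integers(1, m + 1))
            kind = rng.integers(0, 2)
            crit = (linear_critical_values(m, crit_alpha, order=lam) if kind
                    else aorc_critical_values(m, crit_alpha, order=lam))
            got = sud_test(p, crit).reject
            want = sud_oracle(p, crit.thresholds, lam)
            np.testing.assert_array_equal(got, want)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=8),
           st.integers(1, 8), st.booleans())
    def test_monotone_in_pvalues(self, grid, lam_raw, use_aorc):
        """Decreasing any single p-value never decreases the rejection count."""
        p = np.array(grid) / 20.0
        m = p.size
        lam = min(lam_raw, m)
        crit = (aorc_critical_values(m, 0.1, order=lam) if use_aorc
                else linear_critical_values(m, 0.1, order=lam))
        base = sud_test(p, crit).num_rejections
        for j in range(m):
            if p[j] == 0:
                continue
            q = p.copy()
            q[j] = max(0.0, q[j] - 0.05)
            assert sud_test(q, crit).num_rejections >= base

    def test_rejection_set_consistency(self, rng):
        """All rejected p-values are <= the cutoff and all others are > it."""
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = np.round(rng.random(m), 2)
            lam = int(rng.integers(1, m + 1))
            crit = aorc_critical_values(m, 0.1, order=lam)
            res = sud_test(p, crit)
            if res.threshold_index is None:
                assert res.num_rejections == 0
            else:
                assert np.all(p[res.reject] <= res.threshold_value)
                assert np.all(p[~res.reject] > res.threshold_value)


class TestLSU:
    def test_worked_examples(self):
        res = lsu_test([0.001, 0.01, 0.02, 0.3, 0.9], 0.05)
        assert res.threshold_index == 3 and res.num_rejections == 3
        assert lsu_test([0.04], 0.05).num_rejections == 1
        assert lsu_test([0.9, 0.8], 0.05).num_rejections == 0

    def test_equals_sud_with_linear_order_m(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 9))
            p = rng.integers(0, 8, size=m) / 7.0
            got = lsu_test(p, 0.1).reject
            want = sud_oracle(p, linear_critical_values(m, 0.1).thresholds, m)
            np.testing.assert_array_equal(got, want)

    def test_null_fdr_matches_level(self, rng):
        """Under m iid uniforms the LSU FDR equals (m0/m)*alpha = alpha exactly."""
        B, m, alpha = 20000, 20, 0.05
        crit = linear_critical_values(m, alpha).thresholds
        u = np.sort(rng.random((B, m)), axis=1)
        ok = u <= crit
        any_pass = ok.any(axis=1)
        # under the complete null every rejection is false, so FDP = 1{R > 0}
        fdp = any_pass.astype(float)
        se = fdp.std(ddof=1) / np.sqrt(B)
        assert abs(fdp.mean() - alpha) <= 3 * se

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            lsu_test([0.5, 1.2], 0.05)
        with pytest.raises(ValueError):
            lsu_test([0.5, np.nan], 0.05)
        with pytest.raises(ValueError):
            lsu_test([], 0.05)
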