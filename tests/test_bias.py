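import itertools
import math

import numpy as np
import pytest
from scipy import stats

from metasynopsis import (
    begg_test,
    bias_checks,
    egger_test,
    fixed_effect_pool,
    select_and_pool,
    sensitivity_suite,
)


def ols_oracle(x, y):
    """Closed-form simple OLS with intercept: (b0, se_b0, two-sided t p)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    b0 = ybar - slope * xbar
    resid = y - b0 - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se_b0 = math.sqrt(s2 * (1 / n + xbar**2 / ((x - xbar) ** 2).sum()))
    p = 2 * stats.t.sf(abs(b0 / se_b0), n - 2)
    return b0, se_b0, p


def kendall_exact_oracle(x, y):
    """Two-sided exact p for Kendall's tau by brute-force permutation."""

    def tau(a, b):
        conc = disc = 0
        for i, j in itertools.combinations(range(len(a)), 2):
            s = (a[i] - a[j]) * (b[i] - b[j])
            conc += s > 0
            disc += s < 0
        return (conc - disc) / (len(a) * (len(a) - 1) / 2)

    observed = tau(x, y)
    count = 0
    total = 0
    for perm in itertools.permutations(x):
        total += 1
        count += abs(tau(perm, y)) >= abs(observed) - 1e-12
    return observed, count / total


class TestEgger:
    def test_constant_effect_gives_zero_intercept(self, make_dataset):
        ses = [0.1, 0.2, 0.3, 0.4, 0.5]
        ds = make_dataset([0.3] * 5, ses)
        intercept, _, _ = egger_test(ds)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_ols_oracle(self, make_dataset):
        thetas = [0.10, 0.25, 0.30, 0.70]
        ses = [0.1, 0.2, 0.4, 0.8]
        ds = make_dataset(thetas, ses)
        intercept, se, p = egger_test(ds)
        x = 1 / np.asarray(ses)
        y = np.asarray(thetas) / np.asarray(ses)
        b0, se_b0, p0 = ols_oracle(x, y)
        assert intercept == pytest.approx(b0, abs=1e-10)
        assert se == pytest.approx(se_b0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_two_studies_not_computable(self, make_dataset):
        assert egger_test(make_dataset([0.1, 0.2], [0.1, 0.2])) is None


class TestBegg:
    def test_constant_effect_gives_zero_tau(self, make_dataset):
        ds = make_dataset([0.3] * 4, [0.1, 0.2, 0.3, 0.4])
        tau, p, _ = begg_test(ds)
        assert tau == 0.0 and p == 1.0

    def test_perfect_concordance_matches_permutation_oracle(self, make_dataset):
        thetas = [-0.30, -0.05, 0.35, 1.10]
        ses = [0.10, 0.20, 0.30, 0.40]
        ds = make_dataset(thetas, ses)
        pooled = fixed_effect_pool(ds)
        v = (np.array(thetas) - pooled.theta_hat) / np.sqrt(
            np.array(ses) ** 2 - pooled.se_hat**2
        )
        assert np.all(np.diff(v) > 0)  # deviates strictly increase with variance
        tau, p, _ = begg_test(ds)
        tau0, p0 = kendall_exact_oracle(list(v), [s**2 for s in ses])
        assert tau == pytest.approx(tau0) == 1.0
        assert p == pytest.approx(p0)

    def test_two_studies_not_computable(self, make_dataset):
        assert begg_test(make_dataset([0.1, 0.2], [0.1, 0.2])) is None

    def test_bundled_result_carries_both_tests(self, make_dataset):
        ds = make_dataset([0.1, 0.4, 0.2, 0.5], [0.1, 0.2, 0.3, 0.4])
        res = bias_checks(ds)
        assert res.computable
        assert res.egger_p is not None and res.begg_p is not None
        assert abs(res.begg_tau) <= 1


class TestSensitivity:
    def test_homogeneous_significant_pool_is_robust(self, make_dataset):
        ds = make_dataset(
            [0.5, 0.52, 0.48, 0.51, 0.49], [0.05] * 5,
            is_first_report=[True, False, False, False, False],
            hwe_p_controls=[0.5, 0.6, 0.7, 0.8, 0.9],
        )
        rep = sensitivity_suite(ds)
        assert rep.robust
        assert len(rep.leave_one_out) == 5
        assert all(r.k == 4 for _, r in rep.leave_one_out)

    def test_single_driving_study_breaks_robustness(self, make_dataset):
        ds = make_dataset([0.5, 0.15, 0.15], [0.05, 0.2, 0.2])
        assert select_and_pool(ds).p < 0.05
        rep = sensitivity_suite(ds)
        assert not rep.robust
        assert rep.drivers == ["s1"]

    def test_missing_first_report_flag_marks_arm_not_evaluable(self, make_dataset):
        ds = make_dataset([0.5, 0.5, 0.5], [0.05] * 3)
        rep = sensitivity_suite(ds)
        assert rep.drop_first_positive is None
        assert any("first-positive" in note for note in rep.notes)

    def test_hwe_violators_are_excluded_from_that_arm(self, make_dataset):
        ds = make_dataset(
            [0.5, 0.5, 0.5, 0.5], [0.05] * 4,
            hwe_p_controls=[0.5, 0.5, 0.001, 0.5],
        )
        rep = sensitivity_suite(ds)
        assert rep.drop_hwe_violations.k == 3

    def test_suite_does_not_mutate_the_full_pool(self, make_dataset):
        ds = make_dataset([0.5, 0.4, 0.6, 0.5], [0.05] * 4)
        before = select_and_pool(ds)
        sensitivity_suite(ds)
        after = select_and_pool(ds)
        assert before == after
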