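"""Small-study bias diagnostics and the three sensitivity re-analyses.

Egger's regression test fits standardized effects ``theta_i / se_i`` against
precisions ``1 / se_i`` by ordinary least squares and tests the intercept
against zero (t, k - 2 df): a constant true effect puts every study on a
line through the origin, so a non-zero intercept signals funnel asymmetry.
Begg's test ranks the variance-stabilized deviates from the fixed-effect
pooled value against the study variances with Kendall's tau. Both tests are
conventionally read at a two-tailed 0.10 level.

The sensitivity suite re-pools a significant dataset k times leaving one
study out, once without the first positive report, and once without studies
whose controls deviate from Hardy-Weinberg equilibrium, and calls the
association robust when every evaluable re-analysis keeps significance with
an unchanged effect direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effects import dataset_effects
from .meta import MetaResult, pool_effects, select_and_pool
from .records import AssociationDataset


@dataclass(frozen=True)
class BiasResult:
    """Egger and Begg test outcomes for one dataset (None when k < 3)."""

    egger_intercept: float | None
    egger_se: float | None
    egger_p: float | None
    begg_tau: float | None
    begg_p: float | None
    significant_at: float = 0.10
    ties_flagged: bool = False

    @property
    def computable(self) -> bool:
        return self.egger_p is not None

    @property
    def any_bias(self) -> bool | None:
        if not self.computable:
            return None
        return self.egger_p < self.significant_at or self.begg_p < self.significant_at


def egger_test(dataset: AssociationDataset) -> tuple[float, float, float] | None:
    """Egger regression intercept, its se, and the two-sided p (t, k-2 df).

    Returns None when fewer than three studies are available.
    """
    thetas, ses = dataset_effects(dataset)
    if len(thetas) < 3:
        return None
    y = thetas / ses
    x = sm.add_constant(1.0 / ses)
    fit = sm.OLS(y, x).fit()
    return float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0])


def begg_test(dataset: AssociationDataset) -> tuple[float, float, bool] | None:
    """Begg rank-correlation test: (Kendall tau, p, ties_flagged).

    Deviates are ``(theta_i - theta_FE) / sqrt(se_i^2 - se_FE^2)`` with the
    fixed-effect pooled value, correlated against the study variances. The
    p-value is exact (pair-permutation distribution) for k <= 8 without
    ties, the normal approximation otherwise; ties fall back to the tau-b
    correction and are flagged. Returns None when k < 3.
    """
    thetas, ses = dataset_effects(dataset)
    k = len(thetas)
    if k < 3:
        return None
    pooled = pool_effects(thetas, ses, method="fixed")
    v = (thetas - pooled.theta_hat) / np.sqrt(ses**2 - pooled.se_hat**2)
    variances = ses**2
    if np.allclose(v, v[0]):
        return 0.0, 1.0, True
    has_ties = len(set(v)) < k or len(set(variances)) < k
    method = "exact" if (k <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(v, variances, method=method)
    return float(res.statistic), float(res.pvalue), has_ties


def bias_checks(dataset: AssociationDataset, significant_at: float = 0.10) -> BiasResult:
    """Bundle both bias tests into a :class:`BiasResult`."""
    egger = egger_test(dataset)
    begg = begg_test(dataset)
    if egger is None or begg is None:
        return BiasResult(None, None, None, None, None, significant_at)
    return BiasResult(
        egger[0], egger[1], egger[2], begg[0], begg[1], significant_at, begg[2]
    )


@dataclass
class SensitivityReport:
    """Outcome of the three sensitivity re-analyses of a significant pool."""

    leave_one_out: list[tuple[str, MetaResult]]
    drop_first_positive: MetaResult | None
    drop_hwe_violations: MetaResult | None
    robust: bool
    drivers: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _repool(dataset: AssociationDataset, keep, switch_i2: float) -> MetaResult | None:
    subset = [r for r in dataset.records if keep(r) and r.is_analyzable]
    if len(subset) < 2:
        return None
    return select_and_pool(dataset.subset(lambda r: keep(r) and r.is_analyzable), switch_i2)


def sensitivity_suite(
    dataset: AssociationDataset,
    alpha: float = 0.05,
    hwe_alpha: float = 0.05,
    switch_i2: float = 50.0,
) -> SensitivityReport:
    """Run leave-one-out, first-positive-excluded and HWE-excluded re-analyses.

    Intended for datasets whose pooled association is significant at
    ``alpha``. The full-data pooled direction is the reference; robustness
    requires every evaluable re-analysis to stay significant in the same
    direction. Arms that cannot be evaluated (no flag carried, or fewer
    than two records left) are noted and excluded from the verdict.
    """
    full = select_and_pool(dataset, switch_i2)
    direction = math.copysign(1.0, full.theta_hat)
    notes: list[str] = []
    drivers: list[str] = []

    def holds(result: MetaResult | None) -> bool | None:
        if result is None:
            return None
        return result.p < alpha and math.copysign(1.0, result.theta_hat) == direction

    loo: list[tuple[str, MetaResult]] = []
    analyzable = [r for r in dataset.records if r.is_analyzable]
    for r in analyzable:
        res = _repool(dataset, lambda rec, rid=r.study_id: rec.study_id != rid, switch_i2)
        if res is None:
            notes.append(f"leave-one-out arm for {r.study_id} not evaluable (k < 2)")
            continue
        loo.append((r.study_id, res))
        if holds(res) is False:
            drivers.append(r.study_id)

    if any(r.is_first_report for r in analyzable):
        no_first = _repool(dataset, lambda rec: not rec.is_first_report, switch_i2)
        if no_first is None:
            notes.append("first-positive arm not evaluable (k < 2 after exclusion)")
    else:
        no_first = None
        notes.append("first-positive arm not evaluable (no record flagged)")

    if any(r.hwe_p_controls is not None for r in analyzable):
        no_hwe = _repool(
            dataset,
            lambda rec: rec.hwe_p_controls is None or rec.hwe_p_controls >= hwe_alpha,
            switch_i2,
        )
        if no_hwe is None:
            notes.append("HWE arm not evaluable (k < 2 after exclusion)")
    else:
        no_hwe = None
        notes.append("HWE arm not evaluable (no control HWE p-values recorded)")

    verdicts = [holds(res) for _, res in loo]
    verdicts += [holds(no_first), holds(no_hwe)]
    evaluable = [v for v in verdicts if v is not None]
    robust = bool(evaluable) and all(evaluable)
    return SensitivityReport(loo, no_first, no_hwe, robust, drivers, notes)
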