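"""Conversion of raw study data to a common (theta, se) effect representation.

Every pooling operation works on a point estimate ``theta`` (log odds ratio
for binary outcomes, standardized mean difference for quantitative traits)
and its standard error. This module derives that pair from whichever form a
study reported — a ratio with its 95% CI, raw genotype counts under the
additive (per-allele) model, or per-genotype means under a co-dominant
contrast — and provides Hardy-Weinberg equilibrium testing of control
genotypes (chi-square and exact).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .records import GenotypeCounts, GroupStats, StudyRecord

#: Two-sided 95% normal quantile, fixed so CI-derived standard errors
#: reproduce to the decimal regardless of the scipy build.
Z_95 = 1.959964


class DomainError(ValueError):
    """Input outside the mathematical domain of the conversion."""


class DegenerateTableError(ValueError):
    """A contingency table or group with no information (zero total)."""


def _z_for_level(level: float) -> float:
    if not 0 < level < 1:
        raise DomainError(f"confidence level must be in (0, 1), got {level}")
    return Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))


def theta_from_ratio_ci(
    or_: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Back-derive (log ratio, se) from a ratio and its confidence interval.

    ``se = (ln U - ln L) / (2 z)`` with ``z`` the two-sided normal quantile
    at ``level``. A point estimate outside its own CI is tolerated with a
    warning (the CI still determines the se); non-positive inputs raise.
    """
    if min(or_, ci_low, ci_high) <= 0:
        raise DomainError(f"ratio and CI bounds must be positive: ({or_}, {ci_low}, {ci_high})")
    if not ci_low < ci_high:
        raise DomainError(f"ci_low must be below ci_high: ({ci_low}, {ci_high})")
    if not ci_low <= or_ <= ci_high:
        warnings.warn(
            f"point estimate {or_} lies outside its CI ({ci_low}, {ci_high}); "
            "using the CI-derived standard error",
            stacklevel=2,
        )
    z = _z_for_level(level)
    return math.log(or_), (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def additive_or_from_counts(
    case_genotypes, ctrl_genotypes
) -> tuple[float, float]:
    """Per-allele (additive) log odds ratio from genotype counts.

    Genotype triples are ordered by effect-allele dose (0, 1, 2). Alleles
    are counted (dose-2 homozygotes contribute two effect alleles), the
    cross-product odds ratio is formed on the resulting 2x2 allele table,
    and ``se = sqrt(1/a + 1/b + 1/c + 1/d)``. A 0.5 continuity correction
    is added to every cell when any cell is zero.
    """
    case = GenotypeCounts(*(int(v) for v in case_genotypes))
    ctrl = GenotypeCounts(*(int(v) for v in ctrl_genotypes))
    if any(c < 0 for c in case + ctrl):
        raise DomainError("genotype counts must be non-negative")
    if case.total == 0 or ctrl.total == 0:
        raise DegenerateTableError("each group needs at least one genotyped subject")
    a, b = float(case.effect_alleles), float(case.other_alleles)
    c, d = float(ctrl.effect_alleles), float(ctrl.other_alleles)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    theta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return theta, se


def smd_from_group_stats(
    g1, g0, hedges: bool = False
) -> tuple[float, float]:
    """Standardized mean difference (Cohen's d) between two genotype groups.

    ``d = (m1 - m0) / s_pooled`` with the df-weighted pooled SD, and
    ``se(d) = sqrt((n1 + n0)/(n1 n0) + d^2 / (2 (n1 + n0)))``. The Hedges
    small-sample correction is available behind ``hedges=True`` but off by
    default.
    """
    g1, g0 = GroupStats(*g1), GroupStats(*g0)
    for g in (g1, g0):
        if g.n < 2:
            raise DomainError(f"each group needs n >= 2, got {g.n}")
        if not g.sd > 0:
            raise DomainError(f"group sd must be positive, got {g.sd}")
    n1, n0 = g1.n, g0.n
    sp2 = ((n1 - 1) * g1.sd**2 + (n0 - 1) * g0.sd**2) / (n1 + n0 - 2)
    if sp2 <= 0:
        raise DegenerateTableError("pooled standard deviation is zero")
    d = (g1.mean - g0.mean) / math.sqrt(sp2)
    if hedges:
        d *= 1 - 3 / (4 * (n1 + n0) - 9)
    se = math.sqrt((n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0)))
    return d, se


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg test outcome for one genotype sample."""

    chi2: float
    p: float
    expected_counts: tuple[float, float, float]
    method: str  # "chi_square" or "exact"

    @property
    def rejected(self) -> bool:
        return self.p < 0.05


def _hwe_chi2(counts: GenotypeCounts) -> tuple[float, tuple[float, float, float]]:
    n = counts.total
    q = counts.effect_alleles / (2 * n)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    chi2 = sum(
        (obs - exp) ** 2 / exp
        for obs, exp in zip(counts, expected)
        if exp > 0
    )
    return float(chi2), expected


def _hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg p-value, conditioning on the allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    totals and sums the probabilities of configurations no more likely than
    the observed one (two-sided).
    """
    n = counts.total
    n_eff = counts.effect_alleles
    n_oth = counts.other_alleles
    rare = min(n_eff, n_oth)
    log_const = gammaln(n_eff + 1) + gammaln(n_oth + 1) + gammaln(n + 1) - gammaln(2 * n + 1)

    def log_prob(het: int) -> float:
        d2 = (n_eff - het) // 2  # effect-allele homozygotes
        d0 = n - het - d2
        return (
            log_const
            + het * math.log(2)
            - gammaln(d0 + 1)
            - gammaln(het + 1)
            - gammaln(d2 + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (counts.dose1 - rare % 2) // 2
    p_obs = probs[obs]
    return min(1.0, float(probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(ctrl_genotypes, method: str = "auto") -> HweResult:
    """Test genotype counts (dose order 0/1/2) for Hardy-Weinberg equilibrium.

    ``method`` is "chi_square", "exact", or "auto" (exact below 200
    subjects, chi-square otherwise). A monomorphic sample is in perfect
    equilibrium by construction and returns p = 1 with a warning.
    """
    counts = GenotypeCounts(*(int(v) for v in ctrl_genotypes))
    if any(c < 0 for c in counts):
        raise DomainError("genotype counts must be non-negative")
    if counts.total == 0:
        raise DegenerateTableError("empty genotype sample")
    if method not in ("auto", "chi_square", "exact"):
        raise ValueError(f"unknown HWE method {method!r}")
    if counts.effect_alleles == 0 or counts.other_alleles == 0:
        warnings.warn("monomorphic sample: HWE test is vacuous", stacklevel=2)
        return HweResult(0.0, 1.0, tuple(float(c) for c in counts), "chi_square")
    if method == "auto":
        method = "exact" if counts.total < 200 else "chi_square"
    chi2, expected = _hwe_chi2(counts)
    if method == "chi_square":
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = _hwe_exact_p(counts)
    return HweResult(chi2, p, expected, method)


def record_theta_se(record: StudyRecord, contrast: str = "additive") -> tuple[float, float]:
    """Resolve a record to (theta, se) using its highest-priority evidence form.

    Priority: reported (theta, se); ratio with CI; genotype counts under the
    additive model; per-genotype group stats under the requested co-dominant
    contrast (dose 2 vs 0 for ``codominant_hom``, dose 1 vs 0 for
    ``codominant_het``).
    """
    basis = record.analysis_basis
    if basis == "theta_se":
        return float(record.theta), float(record.se)
    if basis == "ratio_ci":
        return theta_from_ratio_ci(record.or_reported, record.ci_low, record.ci_high)
    if basis == "genotype_counts":
        if contrast != "additive":
            raise DomainError(
                "genotype-count records are converted under the additive model only"
            )
        return additive_or_from_counts(record.case_genotypes, record.control_genotypes)
    if basis == "group_stats":
        dose = 2 if contrast != "codominant_het" else 1
        gs = record.group_stats
        if dose not in gs or 0 not in gs:
            raise DomainError(f"group_stats lack doses needed for contrast {contrast!r}")
        return smd_from_group_stats(gs[dose], gs[0])
    raise DomainError(f"record {record.study_id!r} is not analyzable")


def dataset_effects(dataset) -> tuple[np.ndarray, np.ndarray]:
    """(thetas, ses) arrays for every analyzable record, in record order."""
    pairs = [
        record_theta_se(r, dataset.contrast) for r in dataset.records if r.is_analyzable
    ]
    if not pairs:
        raise DomainError("dataset has no analyzable records")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]
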