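"""Cumulative-evidence grading: Venice criteria, FPRP, and their combination.

The Venice framework grades an association A/B/C on three axes — amount of
evidence, replication, protection from bias — and maps the triplet to a
category: *strong* when all three are A, *weak* when any is C, *moderate*
otherwise.

The false-positive report probability (FPRP) of a significant finding is

    FPRP = alpha (1 - pi) / (alpha (1 - pi) + (1 - beta) pi)

where ``alpha`` is the observed significance level, ``pi`` the prior
probability of a true association, and ``1 - beta`` the power to detect a
target odds ratio ``OR1`` at level ``alpha``:

    1 - beta = Phi(|ln OR1|/se - z_{1-alpha/2}) + Phi(-|ln OR1|/se - z_{1-alpha/2})

Because only |ln OR1| enters, the reciprocal convention for protective
effects is automatic. FPRP below 0.05 is strong, between 0.05 and 0.20
moderate, above 0.20 weak evidence of a true association; the final
cumulative label shifts the Venice category up one level when FPRP evidence
is strong and down one level when it is weak, saturating at the ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .bias import BiasResult, SensitivityReport
from .effects import theta_from_ratio_ci
from .meta import MetaResult
from .records import AssociationDataset

LEVELS = ("weak", "moderate", "strong")
LETTERS = ("A", "B", "C")


@dataclass(frozen=True)
class GradeTriplet:
    """Venice letters for amount of evidence, replication, bias protection.

    ``None`` marks an axis that could not be graded; it renders as "-" and
    behaves as a non-A, non-C neutral grade in the category mapping.
    """

    amount: str | None
    replication: str | None
    bias_protection: str | None

    def __post_init__(self):
        for letter in (self.amount, self.replication, self.bias_protection):
            if letter is not None and letter not in LETTERS:
                raise ValueError(f"Venice grades are A/B/C or None, got {letter!r}")

    @property
    def letters(self) -> tuple[str | None, str | None, str | None]:
        return (self.amount, self.replication, self.bias_protection)

    def render(self) -> str:
        return "".join(letter or "-" for letter in self.letters)

    @classmethod
    def parse(cls, text: str) -> "GradeTriplet":
        text = text.strip()
        if len(text) != 3:
            raise ValueError(f"a Venice grade has three characters, got {text!r}")
        return cls(*(None if ch == "-" else ch.upper() for ch in text))


def venice_category(triplet: GradeTriplet) -> str:
    """Map a grade triplet to strong/moderate/weak."""
    letters = triplet.letters
    if "C" in letters:
        return "weak"
    if all(letter == "A" for letter in letters):
        return "strong"
    return "moderate"


@dataclass(frozen=True)
class VeniceThresholds:
    """Configurable sub-criteria thresholds (HuGENet-style defaults).

    Amount of evidence is graded on the total effect-allele count among
    cases and controls; replication on I^2 given at least ``min_datasets``
    datasets; bias protection on the Egger/Begg tests at ``bias_alpha``
    and the sensitivity verdict.
    """

    amount_a: float = 1000.0  # grade A above this many effect alleles
    amount_b: float = 100.0  # grade B from here to amount_a; C below
    replication_a: float = 25.0  # I^2 (%) below which replication is A
    replication_b: float = 50.0  # I^2 (%) up to which replication is B
    min_datasets: int = 3
    bias_alpha: float = 0.10


def grade_venice(
    meta: MetaResult,
    bias: BiasResult | None,
    sens: SensitivityReport | None,
    dataset: AssociationDataset | None = None,
    *,
    maf: float | None = None,
    thresholds: VeniceThresholds | None = None,
) -> GradeTriplet:
    """Grade one pooled association on the three Venice axes.

    The effect-allele count comes from the dataset's genotype counts when
    available, otherwise from ``2 * maf * (cases + controls)`` when ``maf``
    and sample sizes are known; an axis with no usable input is left
    ungraded (None).
    """
    t = thresholds or VeniceThresholds()

    n_alleles: float | None = None
    if dataset is not None and dataset.effect_allele_total is not None:
        n_alleles = float(dataset.effect_allele_total)
    elif dataset is not None and maf is not None:
        totals = [
            (r.n_cases or 0) + (r.n_controls or 0) for r in dataset.records
        ]
        if any(totals):
            n_alleles = 2.0 * maf * sum(totals)
    if n_alleles is None:
        amount = None
    elif n_alleles > t.amount_a:
        amount = "A"
    elif n_alleles >= t.amount_b:
        amount = "B"
    else:
        amount = "C"

    if meta.i2 is None:
        replication = None
    elif meta.i2 < t.replication_a:
        replication = "A" if meta.k >= t.min_datasets else "B"
    elif meta.i2 <= t.replication_b:
        replication = "B"
    else:
        replication = "C"

    if bias is None and sens is None:
        protection = None
    else:
        flagged = bias is not None and bias.computable and bias.any_bias
        fragile = sens is not None and not sens.robust
        if flagged or fragile:
            protection = "C"
        elif (
            bias is not None
            and bias.computable
            and sens is not None
            and sens.robust
        ):
            protection = "A"
        else:
            protection = "B"

    return GradeTriplet(amount, replication, protection)


@dataclass(frozen=True)
class FPRPResult:
    """FPRP of one significant association."""

    alpha: float
    pi: float
    or1: float
    power: float
    value: float
    category: str


def power_at_or(se: float, alpha: float, or1: float) -> float:
    """Power of a Wald test at level ``alpha`` to detect ``or1`` given ``se``.

    Both rejection tails are included; only |ln OR1| matters, so 1.2 and
    1/1.2 give identical power.
    """
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if or1 <= 0 or or1 == 1:
        raise ValueError(f"or1 must be a positive ratio != 1, got {or1}")
    z = float(stats.norm.isf(alpha / 2))  # isf stays finite for very small alpha
    shift = abs(math.log(or1)) / se
    return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))


def fprp_category(value: float) -> str:
    """Strong below 0.05, moderate to 0.20, weak above.

    Boundary values go to the less-noteworthy side (0.05 is moderate,
    0.20 is weak).
    """
    if not 0 <= value <= 1:
        raise ValueError(f"FPRP must be in [0, 1], got {value}")
    if value < 0.05:
        return "strong"
    if value < 0.20:
        return "moderate"
    return "weak"


def fprp(alpha: float, power: float, pi: float = 0.05, *, or1: float = 1.2) -> FPRPResult:
    """Evaluate the FPRP formula and classify the result."""
    for name, v in (("alpha", alpha), ("pi", pi)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    if not 0 < power <= 1:  # power saturates to 1.0 for tiny standard errors
        raise ValueError(f"power must be in (0, 1], got {power}")
    value = alpha * (1 - pi) / (alpha * (1 - pi) + power * pi)
    return FPRPResult(alpha, pi, or1, power, value, fprp_category(value))


def fprp_from_summary(
    or_: float,
    ci_low: float,
    ci_high: float,
    p: float | None = None,
    *,
    alpha_source: str = "reported_p",
    or1: float = 1.2,
    pi: float = 0.05,
) -> FPRPResult:
    """FPRP from a pooled ratio, its 95% CI, and (optionally) its p-value.

    ``alpha_source`` selects the observed significance level: the reported
    p-value ("reported_p") or the level implied by the CI-derived z
    statistic ("ci_implied", ``alpha = 2 (1 - Phi(|ln OR| / se))``). The
    standard error always comes from the CI.
    """
    theta, se = theta_from_ratio_ci(or_, ci_low, ci_high)
    if alpha_source == "reported_p":
        if p is None:
            raise ValueError("alpha_source='reported_p' needs a p-value")
        alpha = p
    elif alpha_source == "ci_implied":
        alpha = 2 * float(stats.norm.sf(abs(theta) / se))
    else:
        raise ValueError(f"unknown alpha_source {alpha_source!r}")
    power = power_at_or(se, alpha, or1)
    return fprp(alpha, power, pi, or1=or1)


@dataclass(frozen=True)
class CumulativeEvidence:
    """Final evidence label after FPRP adjustment of the Venice category."""

    venice_category: str
    fprp_category: str
    final: str


def combine_evidence(venice_cat: str, fprp_cat: str) -> CumulativeEvidence:
    """Shift the Venice category by the FPRP verdict, saturating at the ends.

    Strong FPRP evidence upgrades one level, weak FPRP evidence downgrades
    one level, moderate leaves the category unchanged.
    """
    for cat in (venice_cat, fprp_cat):
        if cat not in LEVELS:
            raise ValueError(f"unknown evidence category {cat!r}")
    idx = LEVELS.index(venice_cat)
    if fprp_cat == "strong":
        idx = min(idx + 1, len(LEVELS) - 1)
    elif fprp_cat == "weak":
        idx = max(idx - 1, 0)
    return CumulativeEvidence(venice_cat, fprp_cat, LEVELS[idx])
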