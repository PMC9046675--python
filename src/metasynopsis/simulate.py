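"""Synthetic study collections with the structure the pipeline assumes.

The binary generator draws, for each study, a true log odds ratio
``theta_i ~ Normal(theta, tau2)``, control genotypes from Hardy-Weinberg
proportions at the configured minor-allele frequency, and case genotypes
from the HWE weights tilted by ``exp(theta_i * dose)`` — the multiplicative
per-allele odds model, under which the allele-count odds ratio converges to
``exp(theta_i)``. Genotype counts are emitted so the effect-size layer
rebuilds each study's OR exactly as it would from published counts.

The quantitative generator assigns genotype groups (HWE sizes) means
shifted by the configured SMD per allele dose, with noisy observed means
and chi-distributed observed SDs.

``inject_small_study_bias`` emulates selective publication: small studies
(top tercile of standard error) that are not one-sided significant in the
true direction are resampled, with probability ``gamma``, until they are —
the classic suppression of null small studies that bends a funnel plot.

All randomness flows through one integer seed per config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import effects
from .records import AssociationDataset, GenotypeCounts, GroupStats, StudyRecord

_DOSES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic study collection.

    Defaults mirror a typical association in this kind of synopsis: five
    datasets per meta-analysis, minor-allele frequency 0.35, case counts in
    the hundreds-to-thousands and control counts up to tens of thousands,
    no true effect and no heterogeneity unless asked for.
    """

    k: int = 5
    theta: float = 0.0  # true log-OR per effect-allele copy
    tau2: float = 0.0  # between-study variance of theta_i
    maf: float = 0.35  # minor-allele frequency in controls
    n_cases_range: tuple[int, int] = (100, 10_000)
    n_controls_range: tuple[int, int] = (500, 50_000)
    bias_gamma: float = 0.0  # suppression strength for null small studies
    outcome_kind: str = "disease"
    smd: float = 0.0  # true SMD of dose-2 vs dose-0 genotypes
    resid_sd: float = 1.0  # residual SD of the quantitative trait
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not 0 < self.maf < 0.5:
            raise ValueError(f"maf must be in (0, 0.5), got {self.maf}")
        for name in ("n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if not 0 <= self.bias_gamma <= 1:
            raise ValueError("bias_gamma must be in [0, 1]")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")


def _hwe_probs(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def _case_probs(maf: float, theta_i: float) -> np.ndarray:
    w = _hwe_probs(maf) * np.exp(theta_i * _DOSES)
    return w / w.sum()


def _draw_binary_study(
    rng: np.random.Generator, cfg: SimConfig, theta_i: float, n_cases: int, n_controls: int
) -> tuple[GenotypeCounts, GenotypeCounts]:
    case = rng.multinomial(n_cases, _case_probs(cfg.maf, theta_i))
    ctrl = rng.multinomial(n_controls, _hwe_probs(cfg.maf))
    return GenotypeCounts(*case.tolist()), GenotypeCounts(*ctrl.tolist())


def _binary_record(
    study_id: str,
    year: int,
    case: GenotypeCounts,
    ctrl: GenotypeCounts,
    variant: str,
    outcome: str,
    outcome_kind: str,
    first: bool,
) -> StudyRecord:
    theta, se = effects.additive_or_from_counts(case, ctrl)
    hwe = effects.hwe_test(ctrl)
    return StudyRecord(
        study_id=study_id,
        variant_id=variant,
        outcome_name=outcome,
        outcome_kind=outcome_kind,
        effect_allele="C",
        other_allele="A",
        effect_scale="log_odds",
        theta=theta,
        se=se,
        n_cases=case.total,
        n_controls=ctrl.total,
        case_genotypes=case,
        control_genotypes=ctrl,
        hwe_p_controls=hwe.p,
        ancestry="synthetic",
        design="case_control",
        year=year,
        is_first_report=first,
    )


def simulate_binary_meta(
    cfg: SimConfig, variant: str = "rs0000001", outcome: str = "synthetic disease"
) -> AssociationDataset:
    """Generate one case-control study collection under the additive model.

    Reproducible for a fixed ``cfg.seed``; applies small-study suppression
    afterwards when ``cfg.bias_gamma > 0``.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.k):
        theta_i = rng.normal(cfg.theta, math.sqrt(cfg.tau2))
        n_cases = int(rng.integers(cfg.n_cases_range[0], cfg.n_cases_range[1] + 1))
        n_controls = int(rng.integers(cfg.n_controls_range[0], cfg.n_controls_range[1] + 1))
        case, ctrl = _draw_binary_study(rng, cfg, theta_i, n_cases, n_controls)
        records.append(
            _binary_record(
                f"study_{i + 1:03d}", 2003 + i, case, ctrl, variant, outcome,
                cfg.outcome_kind, first=(i == 0),
            )
        )
    dataset = AssociationDataset(variant, outcome, records, cfg.outcome_kind, "additive")
    if cfg.bias_gamma > 0:
        dataset = inject_small_study_bias(dataset, cfg.bias_gamma, cfg, rng=rng)
    return dataset


def inject_small_study_bias(
    dataset: AssociationDataset,
    gamma: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> AssociationDataset:
    """Suppress null small studies to create funnel asymmetry.

    Small studies are the top tercile of standard errors. Each one that is
    not one-sided significant (0.05) in the true effect direction is, with
    probability ``gamma``, replaced by redraws of the same-size study until
    a non-null result appears. ``gamma = 0`` is the identity.
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    if not dataset.records or gamma == 0:
        return dataset
    if cfg.theta == 0:
        raise ValueError("suppression needs a non-zero true effect direction")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    direction = math.copysign(1.0, cfg.theta)
    z_crit = 1.6448536269514722  # one-sided 0.05 normal quantile

    ses = np.array([r.se for r in dataset.records])
    cut = np.quantile(ses, 2 / 3)

    def is_null(theta: float, se: float) -> bool:
        return direction * theta / se < z_crit

    new_records = []
    for r in dataset.records:
        if r.se >= cut and is_null(r.theta, r.se) and rng.random() < gamma:
            for _ in range(max_tries):
                theta_i = rng.normal(cfg.theta, math.sqrt(cfg.tau2))
                case, ctrl = _draw_binary_study(rng, cfg, theta_i, r.n_cases, r.n_controls)
                theta, se = effects.additive_or_from_counts(case, ctrl)
                if not is_null(theta, se):
                    hwe = effects.hwe_test(ctrl)
                    r = dc_replace(
                        r, theta=theta, se=se, case_genotypes=case,
                        control_genotypes=ctrl, hwe_p_controls=hwe.p,
                    )
                    break
        new_records.append(r)
    return AssociationDataset(
        dataset.variant_id, dataset.outcome_name, new_records,
        dataset.outcome_kind, dataset.contrast,
    )


def simulate_quantitative_meta(
    cfg: SimConfig, variant: str = "rs0000001", outcome: str = "synthetic trait"
) -> AssociationDataset:
    """Generate per-genotype summary statistics for a quantitative trait.

    Group means rise by ``smd * resid_sd / 2`` per allele dose (so the
    dose-2 vs dose-0 contrast has the configured SMD), with per-study
    heterogeneity ``tau2`` on the SMD scale. Observed means get sampling
    noise ``resid_sd / sqrt(n_g)`` and observed SDs are chi-distributed.
    """
    if cfg.resid_sd == 0:
        raise ValueError("resid_sd must be positive for a quantitative trait")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.k):
        smd_i = rng.normal(cfg.smd, math.sqrt(cfg.tau2))
        n_total = int(rng.integers(cfg.n_controls_range[0], cfg.n_controls_range[1] + 1))
        sizes = rng.multinomial(n_total, _hwe_probs(cfg.maf))
        sizes = np.maximum(sizes, 2)  # degenerate tiny groups still need a variance
        stats = {}
        for dose, n_g in zip((0, 1, 2), sizes):
            true_mean = smd_i * cfg.resid_sd * dose / 2
            obs_mean = rng.normal(true_mean, cfg.resid_sd / math.sqrt(n_g))
            obs_var = cfg.resid_sd**2 * rng.chisquare(n_g - 1) / (n_g - 1)
            stats[dose] = GroupStats(obs_mean, math.sqrt(obs_var), int(n_g))
        records.append(
            StudyRecord(
                study_id=f"study_{i + 1:03d}",
                variant_id=variant,
                outcome_name=outcome,
                outcome_kind="continuous_phenotype",
                effect_allele="C",
                other_allele="A",
                effect_scale="smd",
                group_stats=stats,
                n_controls=n_total,
                ancestry="synthetic",
                design="cross_sectional",
                year=2003 + i,
                is_first_report=(i == 0),
            )
        )
    return AssociationDataset(
        variant, outcome, records, "continuous_phenotype", "codominant_hom"
    )
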