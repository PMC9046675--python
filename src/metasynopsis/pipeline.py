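"""End-to-end orchestration: study table -> per-association evidence reports.

``run_pipeline`` reads a study-level extraction sheet, harmonizes allele
orientation, partitions records into variant-outcome datasets, pools each
eligible dataset with the heterogeneity-driven model switch, and — for
associations significant at the configured alpha — runs the bias tests,
the sensitivity suite, Venice grading, FPRP, and the combination rule.
Each grading decision is logged with the rule that triggered it, and the
whole run is deterministic for fixed inputs and config.

``replay_pooled`` drives only the evidence-grading stages from published
pooled rows (printed OR, CI, p, I^2, Venice letters, FPRP), which is how
the packaged fixture tables are consumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .bias import BiasResult, SensitivityReport, bias_checks, sensitivity_suite
from .config import SynopsisConfig
from .grading import (
    CumulativeEvidence,
    FPRPResult,
    GradeTriplet,
    combine_evidence,
    fprp,
    fprp_category,
    fprp_from_summary,
    grade_venice,
    power_at_or,
    venice_category,
)
from .io import PooledRow, read_study_table
from .meta import MetaResult, select_and_pool
from .records import AssociationDataset, group_into_datasets, orient_to_effect_allele

log = logging.getLogger("metasynopsis")


@dataclass
class AssociationReport:
    """Everything the synopsis reports about one variant-outcome pair."""

    variant_id: str
    outcome_name: str
    outcome_kind: str
    k: int
    n_cases: int | None
    n_controls: int | None
    meta: MetaResult
    bias: BiasResult | None = None
    sensitivity: SensitivityReport | None = None
    venice: GradeTriplet | None = None
    fprp: FPRPResult | None = None
    cumulative: CumulativeEvidence | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.meta.p < 0.05

    def to_dict(self) -> dict:
        out = {
            "variant": self.variant_id,
            "outcome": self.outcome_name,
            "outcome_kind": self.outcome_kind,
            "datasets": self.k,
            "cases": self.n_cases,
            "controls": self.n_controls,
            "meta": {
                "effect": self.meta.effect,
                "ci_low": self.meta.ci_low,
                "ci_high": self.meta.ci_high,
                "p": self.meta.p,
                "Q": self.meta.Q,
                "i2": self.meta.i2,
                "tau2": self.meta.tau2,
                "model": self.meta.model,
            },
        }
        if self.bias is not None:
            out["bias"] = {
                "egger": {
                    "intercept": self.bias.egger_intercept,
                    "se": self.bias.egger_se,
                    "p": self.bias.egger_p,
                },
                "begg": {"tau": self.bias.begg_tau, "p": self.bias.begg_p},
            }
        if self.sensitivity is not None:
            out["sensitivity"] = {
                "robust": self.sensitivity.robust,
                "drivers": self.sensitivity.drivers,
                "notes": self.sensitivity.notes,
            }
        if self.venice is not None:
            out["grading"] = {
                "venice": self.venice.render(),
                "venice_category": self.cumulative.venice_category,
                "fprp": {
                    "alpha": self.fprp.alpha,
                    "power": self.fprp.power,
                    "value": self.fprp.value,
                    "category": self.fprp.category,
                },
                "cumulative": self.cumulative.final,
            }
        out["notes"] = self.notes
        return out


def _grade_dataset(
    dataset: AssociationDataset, meta: MetaResult, cfg: SynopsisConfig
) -> tuple[BiasResult, SensitivityReport, GradeTriplet, FPRPResult, CumulativeEvidence]:
    bias = bias_checks(dataset, cfg.bias_alpha)
    sens = sensitivity_suite(dataset, cfg.alpha, cfg.hwe_alpha, cfg.switch_i2)
    maf = cfg.mafs.get(dataset.variant_id)
    triplet = grade_venice(meta, bias, sens, dataset, maf=maf, thresholds=cfg.venice)
    vcat = venice_category(triplet)
    power = power_at_or(meta.se_hat, meta.p, cfg.fprp_or1)
    fp = fprp(meta.p, power, cfg.fprp_pi, or1=cfg.fprp_or1)
    comb = combine_evidence(vcat, fp.category)
    log.info(
        "%s/%s: venice=%s (%s), fprp=%.4g (%s) -> %s",
        dataset.variant_id, dataset.outcome_name, triplet.render(), vcat,
        fp.value, fp.category, comb.final,
    )
    return bias, sens, triplet, fp, comb


def run_pipeline(
    studies_path, config: SynopsisConfig | str | None = None
) -> list[AssociationReport]:
    """Full synopsis over a studies.tsv table.

    Returns one report per eligible dataset (at least ``min_datasets``
    analyzable records); grading blocks are attached only when the pooled
    association is significant at the configured two-sided alpha.
    """
    if config is None:
        cfg = SynopsisConfig()
    elif isinstance(config, SynopsisConfig):
        cfg = config
    else:
        cfg = SynopsisConfig.from_yaml(config)

    result = read_study_table(studies_path)
    for issue in result.issues:
        log.warning("line %d: %s", issue.line, issue.message)
    records = []
    for r in result.records:
        target = cfg.effect_alleles.get(r.variant_id)
        records.append(orient_to_effect_allele(r, target) if target else r)

    reports: list[AssociationReport] = []
    for dataset in group_into_datasets(records):
        if dataset.n_analyzable < cfg.min_datasets:
            log.info(
                "%s/%s skipped: %d analyzable dataset(s) < %d",
                dataset.variant_id, dataset.outcome_name,
                dataset.n_analyzable, cfg.min_datasets,
            )
            continue
        pool = dataset.subset(lambda r: r.is_analyzable)
        meta = select_and_pool(pool, cfg.switch_i2)
        report = AssociationReport(
            variant_id=dataset.variant_id,
            outcome_name=dataset.outcome_name,
            outcome_kind=dataset.outcome_kind,
            k=meta.k,
            n_cases=sum(r.n_cases or 0 for r in pool.records) or None,
            n_controls=sum(r.n_controls or 0 for r in pool.records) or None,
            meta=meta,
        )
        if meta.p < cfg.alpha:
            (report.bias, report.sensitivity, report.venice,
             report.fprp, report.cumulative) = _grade_dataset(pool, meta, cfg)
        else:
            report.notes.append(f"not significant at alpha={cfg.alpha}; grading skipped")
        reports.append(report)
    if not reports:
        log.warning("no eligible datasets found in %s", studies_path)
    return reports


def count_significant(items, alpha: float = 0.05) -> tuple[int, int]:
    """(total, significant) association counts at two-sided ``alpha``.

    Accepts :class:`AssociationReport` or :class:`~metasynopsis.io.PooledRow`
    collections.
    """
    items = list(items)
    if not items:
        raise ValueError("no associations to count")

    def pvalue(item):
        return item.meta.p if isinstance(item, AssociationReport) else item.p

    return len(items), sum(pvalue(i) < alpha for i in items)


@dataclass(frozen=True)
class ReplayResult:
    """Evidence-combination replay of one published pooled row."""

    row: PooledRow
    venice_category: str
    fprp_category: str
    predicted: str
    printed: str | None

    @property
    def agrees(self) -> bool | None:
        if self.printed is None:
            return None
        return self.predicted == self.printed.lower()


def replay_pooled(rows: list[PooledRow]) -> list[ReplayResult]:
    """Re-run Venice category -> FPRP category -> combination from printed rows.

    Rows without a printed grade or FPRP (the non-significant ones) are
    skipped. Censored FPRP values ("<0.001") are classified at their bound,
    which cannot change the category across the 0.05 cutoff.
    """
    out = []
    for row in rows:
        if row.venice is None or row.fprp is None:
            continue
        vcat = venice_category(GradeTriplet.parse(row.venice))
        fcat = fprp_category(row.fprp)
        comb = combine_evidence(vcat, fcat)
        out.append(ReplayResult(row, vcat, fcat, comb.final, row.cumulative))
    return out


def recompute_fprp(row: PooledRow, cfg: SynopsisConfig | None = None) -> FPRPResult:
    """FPRP of a published pooled row from its printed OR, CI and p."""
    cfg = cfg or SynopsisConfig()
    return fprp_from_summary(
        row.or_, row.ci_low, row.ci_high, row.p,
        alpha_source=cfg.fprp_alpha_source, or1=cfg.fprp_or1, pi=cfg.fprp_pi,
    )


def reports_to_table(reports: list[AssociationReport]) -> pd.DataFrame:
    """Summary table mirroring the published synopsis layout."""
    rows = []
    for r in reports:
        rows.append(
            {
                "variant": r.variant_id,
                "outcome": r.outcome_name,
                "datasets": r.k,
                "cases": r.n_cases,
                "controls": r.n_controls,
                "OR": round(r.meta.effect, 3),
                "ci_low": round(r.meta.ci_low, 3),
                "ci_high": round(r.meta.ci_high, 3),
                "p": r.meta.p,
                "i2": None if r.meta.i2 is None else round(r.meta.i2, 1),
                "model": r.meta.model,
                "venice": r.venice.render() if r.venice else "",
                "fprp": round(r.fprp.value, 3) if r.fprp else "",
                "cumulative": r.cumulative.final.capitalize() if r.cumulative else "",
            }
        )
    return pd.DataFrame(rows)


def reports_to_json(reports: list[AssociationReport], path=None) -> str:
    """Serialize reports (sorted stably) to JSON; optionally write to disk."""
    payload = json.dumps([r.to_dict() for r in reports], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload
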