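"""Core record types for study-level genetic-association data.

A field synopsis pools, for every variant-outcome pair, the effect estimates
reported by each eligible study. :class:`StudyRecord` holds one study's
contribution in whichever form the publication provided it — a ready
(theta, se) pair, a ratio with its confidence interval, raw genotype counts,
or per-genotype means for a quantitative trait. :class:`AssociationDataset`
is the per-variant, per-outcome collection consumed by the pooling engine.

All effects are expressed per copy of a designated *effect allele* (the
minor allele in the reference population). Records reported on the opposite
allele are flipped with :func:`orient_to_effect_allele`, which is an
involution: applying it twice returns the original record.

Genotype-keyed quantities use the effect-allele dose (0, 1, 2) rather than
letter labels, so orientation is an unambiguous dose reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

OUTCOME_KINDS = ("disease", "categorical_phenotype", "continuous_phenotype")
EFFECT_SCALES = ("log_odds", "smd")
DESIGNS = ("case_control", "cross_sectional", "longitudinal")
CONTRASTS = ("additive", "codominant_hom", "codominant_het")


class RecordError(ValueError):
    """A record violates one of its structural invariants."""


class AlleleMismatchError(ValueError):
    """The requested effect allele is not one of the record's two alleles."""


class DuplicateRecordError(ValueError):
    """Two records share the same (study_id, variant_id, outcome_name) key."""

    def __init__(self, collisions: list[tuple[str, str, str]]):
        self.collisions = list(collisions)
        super().__init__(f"duplicate study records: {self.collisions}")


class GenotypeCounts(NamedTuple):
    """Genotype counts ordered by effect-allele dose (0, 1, 2 copies)."""

    dose0: int
    dose1: int
    dose2: int

    @property
    def total(self) -> int:
        return self.dose0 + self.dose1 + self.dose2

    @property
    def effect_alleles(self) -> int:
        """Number of effect-allele copies in the sample."""
        return 2 * self.dose2 + self.dose1

    @property
    def other_alleles(self) -> int:
        return 2 * self.dose0 + self.dose1

    def flipped(self) -> "GenotypeCounts":
        return GenotypeCounts(self.dose2, self.dose1, self.dose0)


class GroupStats(NamedTuple):
    """Per-genotype summary of a quantitative trait."""

    mean: float
    sd: float
    n: int


def _as_counts(value) -> GenotypeCounts | None:
    if value is None:
        return None
    counts = GenotypeCounts(*(int(v) for v in value))
    if any(c < 0 for c in counts):
        raise RecordError(f"negative genotype count in {tuple(counts)}")
    return counts


@dataclass(frozen=True)
class StudyRecord:
    """One study's effect estimate for one variant-outcome pair.

    Exactly one of the four evidence forms makes the record analyzable,
    checked in priority order: (theta, se); (or_reported, ci_low, ci_high);
    genotype counts; per-genotype group stats. Records carrying none of
    them (for example a bare p-value) are retained but non-poolable.
    """

    study_id: str
    variant_id: str
    outcome_name: str
    outcome_kind: str = "disease"
    effect_allele: str | None = None
    other_allele: str | None = None
    effect_scale: str = "log_odds"
    theta: float | None = None
    se: float | None = None
    or_reported: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_reported: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    case_genotypes: GenotypeCounts | None = None
    control_genotypes: GenotypeCounts | None = None
    group_stats: dict[int, GroupStats] | None = None
    hwe_p_controls: float | None = None
    ancestry: str | None = None
    design: str = "case_control"
    year: int | None = None
    is_first_report: bool = False
    pmid: str | None = None

    def __post_init__(self):
        if self.outcome_kind not in OUTCOME_KINDS:
            raise RecordError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.effect_scale not in EFFECT_SCALES:
            raise RecordError(f"unknown effect_scale {self.effect_scale!r}")
        if self.design not in DESIGNS:
            raise RecordError(f"unknown design {self.design!r}")
        if self.se is not None and not self.se > 0:
            raise RecordError(f"se must be positive, got {self.se}")
        if self.theta is not None and self.se is None and self.or_reported is None:
            # theta without any dispersion information is non-poolable but legal
            pass
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low < self.ci_high:
                raise RecordError(
                    f"ci_low must be below ci_high, got ({self.ci_low}, {self.ci_high})"
                )
        if self.effect_scale == "log_odds":
            for name in ("or_reported", "ci_low", "ci_high"):
                v = getattr(self, name)
                if v is not None and not v > 0:
                    raise RecordError(f"{name} must be positive on the ratio scale, got {v}")
        for v in (self.p_reported, self.hwe_p_controls):
            if v is not None and not 0 <= v <= 1:
                raise RecordError(f"probability outside [0, 1]: {v}")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RecordError(f"{name} must be non-negative, got {v}")
        object.__setattr__(self, "case_genotypes", _as_counts(self.case_genotypes))
        object.__setattr__(self, "control_genotypes", _as_counts(self.control_genotypes))
        if self.group_stats is not None:
            gs = {int(k): GroupStats(*v) for k, v in self.group_stats.items()}
            if not set(gs) <= {0, 1, 2}:
                raise RecordError(f"group_stats keys must be allele doses 0/1/2, got {set(gs)}")
            object.__setattr__(self, "group_stats", gs)

    @property
    def alleles(self) -> tuple[str | None, str | None]:
        return (self.effect_allele, self.other_allele)

    @property
    def analysis_basis(self) -> str | None:
        """Which evidence form the effect-size layer will use, or None."""
        if self.theta is not None and self.se is not None:
            return "theta_se"
        if None not in (self.or_reported, self.ci_low, self.ci_high):
            return "ratio_ci"
        if self.case_genotypes is not None and self.control_genotypes is not None:
            return "genotype_counts"
        if self.group_stats:
            return "group_stats"
        return None

    @property
    def is_analyzable(self) -> bool:
        return self.analysis_basis is not None

    @property
    def effect_allele_total(self) -> int | None:
        """Total effect-allele copies across cases and controls, if counted."""
        if self.case_genotypes is None or self.control_genotypes is None:
            return None
        return self.case_genotypes.effect_alleles + self.control_genotypes.effect_alleles


def orient_to_effect_allele(record: StudyRecord, target_allele: str) -> StudyRecord:
    """Express ``record`` per copy of ``target_allele``.

    Identity when the record is already oriented; otherwise the effect is
    negated on the log/SMD scale, ratios and their CI bounds are inverted
    (bounds swapped), genotype counts and group stats are dose-reversed.
    Standard errors, p-values and totals are untouched, and the operation
    is an involution.
    """
    if record.effect_allele == target_allele:
        return record
    if record.other_allele != target_allele:
        raise AlleleMismatchError(
            f"{target_allele!r} is not an allele of {record.variant_id} "
            f"({record.effect_allele}/{record.other_allele})"
        )
    changes: dict = {
        "effect_allele": record.other_allele,
        "other_allele": record.effect_allele,
    }
    if record.theta is not None:
        changes["theta"] = -record.theta
    if record.or_reported is not None:
        changes["or_reported"] = 1.0 / record.or_reported
    if record.ci_low is not None and record.ci_high is not None:
        if record.effect_scale == "log_odds":
            changes["ci_low"] = 1.0 / record.ci_high
            changes["ci_high"] = 1.0 / record.ci_low
        else:
            changes["ci_low"] = -record.ci_high
            changes["ci_high"] = -record.ci_low
    if record.case_genotypes is not None:
        changes["case_genotypes"] = record.case_genotypes.flipped()
    if record.control_genotypes is not None:
        changes["control_genotypes"] = record.control_genotypes.flipped()
    if record.group_stats is not None:
        changes["group_stats"] = {2 - dose: gs for dose, gs in record.group_stats.items()}
    return replace(record, **changes)


@dataclass
class AssociationDataset:
    """All study records for one variant-outcome pair under one contrast."""

    variant_id: str
    outcome_name: str
    records: list[StudyRecord]
    outcome_kind: str = "disease"
    contrast: str = "additive"

    def __post_init__(self):
        if not self.records:
            raise RecordError("a dataset needs at least one record")
        if self.contrast not in CONTRASTS:
            raise RecordError(f"unknown contrast {self.contrast!r}")
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordError(f"duplicate study_ids within dataset: {dupes}")
        for r in self.records:
            if r.variant_id != self.variant_id or r.outcome_name != self.outcome_name:
                raise RecordError("all records must share the dataset's variant and outcome")
        scales = {r.effect_scale for r in self.records}
        if len(scales) > 1:
            raise RecordError(f"mixed effect scales in one dataset: {scales}")

    @property
    def k(self) -> int:
        return len(self.records)

    @property
    def effect_scale(self) -> str:
        return self.records[0].effect_scale

    @property
    def n_analyzable(self) -> int:
        return sum(r.is_analyzable for r in self.records)

    @property
    def eligible(self) -> bool:
        """Eligible for a main meta-analysis: at least three analyzable datasets."""
        return self.n_analyzable >= 3

    @property
    def effect_allele_total(self) -> int | None:
        totals = [r.effect_allele_total for r in self.records]
        if any(t is None for t in totals):
            return None
        return sum(totals)

    def subset(self, keep) -> "AssociationDataset":
        """New dataset restricted to records for which ``keep(record)`` is true."""
        kept = [r for r in self.records if keep(r)]
        return AssociationDataset(
            self.variant_id, self.outcome_name, kept, self.outcome_kind, self.contrast
        )


def group_into_datasets(records: list[StudyRecord]) -> list[AssociationDataset]:
    """Partition harmonized records by (variant, outcome) into datasets.

    Every record lands in exactly one dataset; datasets with fewer than three
    analyzable records are retained but flagged ineligible via
    :attr:`AssociationDataset.eligible`. Duplicate (study, variant, outcome)
    keys raise :class:`DuplicateRecordError` listing the collisions.
    """
    seen: set[tuple[str, str, str]] = set()
    collisions = []
    for r in records:
        key = (r.study_id, r.variant_id, r.outcome_name)
        if key in seen:
            collisions.append(key)
        seen.add(key)
    if collisions:
        raise DuplicateRecordError(collisions)

    groups: dict[tuple[str, str], list[StudyRecord]] = {}
    for r in records:
        groups.setdefault((r.variant_id, r.outcome_name), []).append(r)
    out = []
    for (variant, outcome), recs in groups.items():
        contrast = "additive" if recs[0].effect_scale == "log_odds" else "codominant_hom"
        out.append(
            AssociationDataset(variant, outcome, recs, recs[0].outcome_kind, contrast)
        )
    return out
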