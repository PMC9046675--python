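"""Delimited-text IO for study tables and the packaged pooled fixtures.

Two schemas live here. ``studies.tsv`` is the study-level extraction sheet
(one row per study x variant x outcome) with a fixed 35-column header;
optional cells are empty strings and CI bounds may arrive either as two
numeric columns or a single "(L, U)" / "L-U" cell in ``ci_low``. The pooled
tables are per-association summary rows (pooled OR, CI, p, I^2, Venice
grade, FPRP, cumulative label) used to replay the evidence-grading stages;
two transcriptions of published disease and phenotype synopses ship with
the package.

Row-level problems are collected with their line numbers rather than
silently skipped; a missing schema column raises immediately.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .effects import theta_from_ratio_ci
from .records import GenotypeCounts, GroupStats, StudyRecord

STUDY_COLUMNS = [
    "study_id", "pmid", "year", "variant_id", "effect_allele", "other_allele",
    "outcome_name", "outcome_kind", "design", "ancestry",
    "or", "ci_low", "ci_high", "beta", "se", "p", "n_cases", "n_controls",
    "case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa",
    "mean_AA", "sd_AA", "n_AA", "mean_Aa", "sd_Aa", "n_Aa",
    "mean_aa", "sd_aa", "n_aa", "hwe_p_controls", "is_first_report",
]

_TRUE = {"1", "true", "yes", "y"}
_CI_CELL = re.compile(
    r"^\(?\s*([0-9.eE+-]+)\s*[,–—-]\s*([0-9.eE+-]+)\s*\)?$"
)


class SchemaError(ValueError):
    """The table header does not match the documented schema."""


@dataclass(frozen=True)
class RowIssue:
    """A data problem on one input row (1-based line number incl. header)."""

    line: int
    message: str


@dataclass
class ReadResult:
    """Parsed records plus any row-level problems encountered."""

    records: list[StudyRecord]
    issues: list[RowIssue]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _parse_ci_cell(text: str) -> tuple[float, float] | None:
    m = _CI_CELL.match(text.strip())
    if m is None:
        return None
    return float(m.group(1)), float(m.group(2))


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def _opt_int(cell: str) -> int | None:
    cell = cell.strip()
    return int(float(cell)) if cell else None


def read_study_table(path, dialect: dict | None = None) -> ReadResult:
    """Read a studies.tsv extraction sheet into :class:`StudyRecord` objects.

    ``dialect`` may override the pandas separator (default tab). Rows
    failing type or invariant checks are reported in ``issues`` with their
    line numbers and excluded; a missing schema column raises
    :class:`SchemaError` naming the column.
    """
    sep = (dialect or {}).get("sep", "\t")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    records: list[StudyRecord] = []
    issues: list[RowIssue] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based plus header
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError) as exc:
            issues.append(RowIssue(line, str(exc)))
    return ReadResult(records, issues)


def _row_to_record(row: pd.Series) -> StudyRecord:
    for col in ("study_id", "variant_id", "outcome_name"):
        if not row[col].strip():
            raise ValueError(f"empty mandatory cell {col!r}")

    ci_low = None
    ci_high = _opt_float(row["ci_high"])
    raw_low = row["ci_low"].strip()
    if raw_low:
        pair = _parse_ci_cell(raw_low)
        if pair is not None and ci_high is None:
            ci_low, ci_high = pair
        else:
            ci_low = float(raw_low)

    genotypes = {}
    for side in ("case", "ctrl"):
        cells = [row[f"{side}_AA"], row[f"{side}_Aa"], row[f"{side}_aa"]]
        vals = [_opt_int(c) for c in cells]
        if all(v is not None for v in vals):
            genotypes[side] = GenotypeCounts(*vals)
        elif any(v is not None for v in vals):
            raise ValueError(f"incomplete {side} genotype counts")
        else:
            genotypes[side] = None

    group_stats = {}
    for dose, label in ((0, "AA"), (1, "Aa"), (2, "aa")):
        mean = _opt_float(row[f"mean_{label}"])
        sd = _opt_float(row[f"sd_{label}"])
        n = _opt_int(row[f"n_{label}"])
        if None not in (mean, sd, n):
            group_stats[dose] = GroupStats(mean, sd, n)
        elif any(v is not None for v in (mean, sd, n)):
            raise ValueError(f"incomplete group stats for genotype {label}")

    beta = _opt_float(row["beta"])
    se = _opt_float(row["se"])
    or_reported = _opt_float(row["or"])
    outcome_kind = row["outcome_kind"].strip() or "disease"
    effect_scale = "smd" if outcome_kind == "continuous_phenotype" else "log_odds"
    if beta is None and or_reported is not None and se is not None:
        # OR with an se but no beta: carry the log-ratio so the pair is poolable
        beta = math.log(or_reported)

    return StudyRecord(
        study_id=row["study_id"].strip(),
        variant_id=row["variant_id"].strip(),
        outcome_name=row["outcome_name"].strip(),
        outcome_kind=outcome_kind,
        effect_allele=row["effect_allele"].strip() or None,
        other_allele=row["other_allele"].strip() or None,
        effect_scale=effect_scale,
        theta=beta,
        se=se,
        or_reported=or_reported,
        ci_low=ci_low,
        ci_high=ci_high,
        p_reported=_opt_float(row["p"]),
        n_cases=_opt_int(row["n_cases"]),
        n_controls=_opt_int(row["n_controls"]),
        case_genotypes=genotypes["case"],
        control_genotypes=genotypes["ctrl"],
        group_stats=group_stats or None,
        hwe_p_controls=_opt_float(row["hwe_p_controls"]),
        ancestry=row["ancestry"].strip() or None,
        design=row["design"].strip() or "case_control",
        year=_opt_int(row["year"]),
        is_first_report=row["is_first_report"].strip().lower() in _TRUE,
        pmid=row["pmid"].strip() or None,
    )


def write_study_table(records: list[StudyRecord], path) -> None:
    """Write records back to the studies.tsv schema (inverse of reading)."""
    rows = []
    for r in records:
        row = {c: "" for c in STUDY_COLUMNS}
        row.update(
            study_id=r.study_id, pmid=r.pmid or "", year=r.year,
            variant_id=r.variant_id, effect_allele=r.effect_allele or "",
            other_allele=r.other_allele or "", outcome_name=r.outcome_name,
            outcome_kind=r.outcome_kind, design=r.design, ancestry=r.ancestry or "",
        )
        row["or"] = r.or_reported
        row["ci_low"], row["ci_high"] = r.ci_low, r.ci_high
        row["beta"], row["se"], row["p"] = r.theta, r.se, r.p_reported
        row["n_cases"], row["n_controls"] = r.n_cases, r.n_controls
        for side, counts in (("case", r.case_genotypes), ("ctrl", r.control_genotypes)):
            if counts is not None:
                row[f"{side}_AA"], row[f"{side}_Aa"], row[f"{side}_aa"] = counts
        if r.group_stats:
            for dose, label in ((0, "AA"), (1, "Aa"), (2, "aa")):
                if dose in r.group_stats:
                    gs = r.group_stats[dose]
                    row[f"mean_{label}"], row[f"sd_{label}"], row[f"n_{label}"] = gs
        row["hwe_p_controls"] = r.hwe_p_controls
        row["is_first_report"] = int(r.is_first_report)
        rows.append(row)
    df = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pooled per-association tables (grading replay inputs)

POOLED_COLUMNS = [
    "variant_id", "major_allele", "minor_allele", "maf", "outcome", "outcome_kind",
    "datasets", "n_cases", "n_controls", "n_total",
    "or", "ci_low", "ci_high", "p", "i2", "het_p", "venice", "fprp", "cumulative",
]


def _censored_float(cell: str) -> tuple[float | None, bool]:
    """Parse a numeric cell that may be left-censored ("<0.001")."""
    cell = cell.strip()
    if not cell:
        return None, False
    if cell.startswith("<"):
        return float(cell[1:]), True
    return float(cell), False


@dataclass(frozen=True)
class PooledRow:
    """One published pooled association with its printed grading columns."""

    variant_id: str
    major_allele: str
    minor_allele: str
    maf: float | None
    outcome: str
    outcome_kind: str
    k: int
    n_cases: int | None
    n_controls: int | None
    n_total: int | None
    or_: float
    ci_low: float
    ci_high: float
    p: float
    i2: float | None
    het_p: float | None
    het_p_censored: bool
    venice: str | None
    fprp: float | None
    fprp_censored: bool
    cumulative: str | None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha

    def theta_se(self) -> tuple[float, float]:
        """(log OR, se) back-derived from the printed CI."""
        return theta_from_ratio_ci(self.or_, self.ci_low, self.ci_high)


def read_pooled_table(path) -> list[PooledRow]:
    """Read a pooled per-association table (the layout of the fixtures)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in POOLED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pooled table missing column(s): {missing}")
    rows = []
    for _, rec in df.iterrows():
        i2 = rec["i2"].strip()
        het_p, het_cens = _censored_float(rec["het_p"])
        fprp_value, fprp_cens = _censored_float(rec["fprp"])
        rows.append(
            PooledRow(
                variant_id=rec["variant_id"],
                major_allele=rec["major_allele"],
                minor_allele=rec["minor_allele"],
                maf=_opt_float(rec["maf"]),
                outcome=rec["outcome"],
                outcome_kind=rec["outcome_kind"],
                k=int(rec["datasets"]),
                n_cases=_opt_int(rec["n_cases"]),
                n_controls=_opt_int(rec["n_controls"]),
                n_total=_opt_int(rec["n_total"]),
                or_=float(rec["or"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                p=float(rec["p"]),
                i2=float(i2) if i2 and i2.upper() != "NA" else None,
                het_p=het_p,
                het_p_censored=het_cens,
                venice=rec["venice"].strip() or None,
                fprp=fprp_value,
                fprp_censored=fprp_cens,
                cumulative=rec["cumulative"].strip() or None,
            )
        )
    return rows


def _data_path(name: str):
    return resources.files("metasynopsis.data").joinpath(name)


def load_disease_table() -> list[PooledRow]:
    """The packaged 27-row pooled disease-association table."""
    return read_pooled_table(_data_path("table1_pooled.tsv"))


def load_phenotype_table() -> list[PooledRow]:
    """The packaged 31-row pooled categorical-phenotype table."""
    return read_pooled_table(_data_path("table2_pooled.tsv"))


def load_phewas_hits():
    """The packaged phenome-wide significant-hit table (18 rows, two variants)."""
    df = pd.read_csv(_data_path("table3_phewas.tsv"), sep="\t", dtype=str)
    df["p"] = df["p"].astype(float)
    df["n_cases"] = df["n_cases"].astype(int)
    return df
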