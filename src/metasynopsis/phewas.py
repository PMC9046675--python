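"""Offline phenome-wide scanning and LD-based variant pruning.

The phenome-wide stage consumes a pre-extracted phenotype summary table
(one row per phenotype with its association p-value) and flags rows passing
a Bonferroni family-wise threshold ``fwer / m``. The LD stage consumes a
square r^2 matrix and collapses variants into clusters connected by
``r^2 > cutoff``, keeping the first variant in input order (or a forced
choice) as each cluster's representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class PhewasRow:
    """One phenotype's summary association for a single variant."""

    phenotype: str
    code: str | None
    effect: float | None
    p: float
    n_cases: int | None = None

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


def bonferroni_threshold(m: int, fwer: float = 0.05) -> float:
    """Per-test threshold controlling the family-wise error over ``m`` tests."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    if not 0 < fwer <= 1:
        raise ValueError(f"fwer must be in (0, 1], got {fwer}")
    return fwer / m


def phewas_scan(rows: list[PhewasRow], fwer: float = 0.05) -> list[PhewasRow]:
    """Rows significant after Bonferroni correction, sorted by ascending p.

    The multiplicity burden is the number of rows scanned, so the threshold
    is ``fwer / len(rows)`` and the significant set grows monotonically
    with ``fwer``.
    """
    if not rows:
        raise ValueError("phewas_scan needs at least one row")
    cut = bonferroni_threshold(len(rows), fwer)
    hits = [r for r in rows if r.p < cut]
    return sorted(hits, key=lambda r: r.p)


def read_phenotype_table(path) -> list[PhewasRow]:
    """Read a phenotypes.tsv summary table (phenotype, code, effect, p, n_cases)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"phenotype", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        rows.append(
            PhewasRow(
                phenotype=rec["phenotype"],
                code=rec.get("code") or None,
                effect=float(rec["effect"]) if rec.get("effect") else None,
                p=float(rec["p"]),
                n_cases=int(rec["n_cases"]) if rec.get("n_cases") else None,
            )
        )
    return rows


@dataclass
class LDMatrix:
    """Square symmetric r^2 matrix over an ordered list of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 must be {m}x{m}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        """Read a square matrix with rsID header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("ld.tsv must have identical row and column variant orders")
        return cls(list(df.columns), df.to_numpy(dtype=float))


def ld_prune(
    matrix: LDMatrix, cutoff: float = 0.8, force_representatives: list[str] | None = None
) -> list[list[str]]:
    """Cluster variants connected by r^2 strictly above ``cutoff``.

    Clusters are the connected components of the thresholded LD graph,
    reported in input order (cluster order by first member; members in
    input order), so the first entry of each cluster is its default
    representative. ``force_representatives`` rotates a named variant to
    the front of its cluster.
    """
    adjacency = matrix.r2 > cutoff
    np.fill_diagonal(adjacency, True)
    n_comp, labels = connected_components(adjacency, directed=False)
    clusters: dict[int, list[str]] = {}
    for vid, label in zip(matrix.variant_ids, labels):
        clusters.setdefault(int(label), []).append(vid)
    ordered = sorted(clusters.values(), key=lambda c: matrix.variant_ids.index(c[0]))
    if force_representatives:
        for cluster in ordered:
            for vid in force_representatives:
                if vid in cluster:
                    cluster.remove(vid)
                    cluster.insert(0, vid)
                    break
    return ordered


def representatives(clusters: list[list[str]]) -> list[str]:
    """The independent variant set: one representative per cluster."""
    return [cluster[0] for cluster in clusters]
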