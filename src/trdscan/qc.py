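"""SNP quality-control cascade for the maternal TRD scan.

Only informative markers enter the likelihood scan.  A SNP survives if,
with strict inequalities throughout:

* it has a nonzero call rate and is polymorphic (pre-filter),
* its family consistency rate (complete AND Mendelian-compatible
  dam-offspring pairs) exceeds ``min_consistency`` (default 0.75),
* its minor-allele frequency exceeds ``min_maf`` (default 0.05),
* its dam heterozygosity exceeds ``min_dam_het`` (default 0.20) — only
  heterozygous dams carry information about the distortion parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family_data import MISSING, FamilySet, GenotypeTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "call_rate",
    "maf",
    "family_consistency_rate",
    "dam_heterozygosity",
    "snp_metrics",
    "apply_filters",
]

STAGES = ("pre_filter", "consistency", "maf", "dam_het")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the SNP filter cascade; all strict (metric > threshold)."""

    min_call_rate: float = 0.0
    min_maf: float = 0.05
    min_consistency: float = 0.75
    min_dam_het: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_consistency", "min_dam_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class FilterReport:
    """Per-stage removal counts (in application order) and per-SNP metrics."""

    stages: list[str] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)
    retained: list[int] = field(default_factory=list)
    metrics: pd.DataFrame | None = None  # snp_id, call_rate, maf, consistency, dam_het

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "removed": self.removed, "retained": self.retained}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def call_rate(snp_row: np.ndarray) -> float:
    """Fraction of individuals with a non-missing call."""
    snp_row = np.asarray(snp_row)
    return float((snp_row != MISSING).sum() / snp_row.size)


def maf(snp_row: np.ndarray) -> float:
    """Frequency of A2 among non-missing calls (table must be recoded).

    NaN for an all-missing SNP (fails any threshold).
    """
    snp_row = np.asarray(snp_row)
    called = snp_row[snp_row != MISSING]
    if called.size == 0:
        return float("nan")
    # count A2 copies directly so small-count fractions (1/20, ...) are exact
    a2 = 2 * int(called.size) - int(called.sum())
    return a2 / (2 * called.size)


def family_consistency_rate(
    snp_row: np.ndarray, families: list[tuple[int, int, str]]
) -> float:
    """Fraction of families that are complete and Mendelian-compatible.

    A pair is incompatible when an opposite-homozygote dam-offspring
    combination occurs (dam 2 with offspring 0 or dam 0 with offspring 2);
    such pairs would have likelihood zero.  ``families`` holds
    (offspring column, dam column, sire variety) index triples.
    """
    if not families:
        return float("nan")
    ok = 0
    for off_col, dam_col, _ in families:
        d, o = int(snp_row[dam_col]), int(snp_row[off_col])
        if d == MISSING or o == MISSING:
            continue
        if (d == 2 and o == 0) or (d == 0 and o == 2):
            continue
        ok += 1
    return ok / len(families)


def dam_heterozygosity(snp_row: np.ndarray, dam_cols) -> float:
    """Fraction of non-missing dams that are heterozygous."""
    dams = np.asarray(snp_row)[np.asarray(list(dam_cols), dtype=int)]
    called = dams[dams != MISSING]
    if called.size == 0:
        return float("nan")
    return float((called == 1).sum() / called.size)


def snp_metrics(table: GenotypeTable, families: FamilySet) -> pd.DataFrame:
    """Per-SNP QC metrics for every SNP in the table."""
    fams = families.resolve(table)
    dam_cols = sorted({dam for _, dam, _ in fams})
    rows = []
    for j in range(table.n_snps):
        row = table.genotypes[j]
        rows.append(
            {
                "snp_id": table.snp_ids[j],
                "call_rate": call_rate(row),
                "maf": maf(row),
                "consistency": family_consistency_rate(row, fams),
                "dam_het": dam_heterozygosity(row, dam_cols) if dam_cols else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def apply_filters(
    table: GenotypeTable, families: FamilySet, config: FilterConfig = FilterConfig()
) -> tuple[GenotypeTable, FilterReport]:
    """Apply the filter cascade in order; returns the surviving table + report.

    Order: pre-filter (zero call rate or monomorphic) -> family consistency
    -> MAF -> dam heterozygosity.  Each stage is a per-SNP predicate, so the
    final retained set is the intersection regardless of order; only the
    per-stage removal counts depend on the order.
    """
    metrics = snp_metrics(table, families)
    cr = metrics["call_rate"].to_numpy()
    mf = metrics["maf"].to_numpy()
    cons = metrics["consistency"].to_numpy()
    het = metrics["dam_het"].to_numpy()

    # NaN metrics (all-missing SNP, no dams) compare False -> SNP fails.
    with np.errstate(invalid="ignore"):
        predicates = {
            "pre_filter": (cr > config.min_call_rate) & (mf > 0.0),
            "consistency": cons > config.min_consistency,
            "maf": mf > config.min_maf,
            "dam_het": het > config.min_dam_het,
        }

    report = FilterReport(metrics=metrics)
    keep = np.ones(table.n_snps, dtype=bool)
    for stage in STAGES:
        newly_removed = keep & ~predicates[stage]
        keep &= predicates[stage]
        report.stages.append(stage)
        report.removed.append(int(newly_removed.sum()))
        report.retained.append(int(keep.sum()))
    return table.subset_snps(keep), report
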