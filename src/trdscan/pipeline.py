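"""Genome-wide SNP-by-SNP scan, FDR correction, and results reporting.

``run_scan`` ties everything together: recode to the major allele, apply
the QC cascade, fit the full and null transmission models at every
retained SNP, test the distortion with the LRT, and correct across SNPs
with Benjamini-Hochberg q-values.  Per-SNP fits are independent, so
results do not depend on scan order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .family_data import FamilySet, GenotypeTable, recode_major_allele
from .likelihood import fit_full, fit_null, lrt_pvalue, tabulate
from .qc import FilterConfig, FilterReport, apply_filters

__all__ = [
    "ScanConfig",
    "RESULT_COLUMNS",
    "scan",
    "run_scan",
    "fdr_qvalues",
    "storey_qvalues",
    "write_results",
    "summarize",
    "manhattan_table",
]

logger = logging.getLogger("trdscan")

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "alpha", "pi_E", "pi_R",
    "lnL_full", "lnL_null", "lrt", "p_value", "q_value",
    "call_rate", "consistency", "maf", "dam_het", "n_families_used",
]


@dataclass(frozen=True)
class ScanConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    fdr_level: float = 0.05
    fdr_method: str = "bh"  # "bh" or "storey"
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0,1)")
        if self.fdr_method not in ("bh", "storey"):
            raise ValueError("fdr_method must be 'bh' or 'storey'")


def fdr_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q(i) = min over j >= i of m * p(j) / j on the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimate pi0 = #{p>lam}/(m(1-lam))."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    pi0 = min(1.0, (p > lam).sum() / (p.size * (1.0 - lam)))
    pi0 = max(pi0, 1.0 / p.size)  # guard: all p small
    return np.minimum(pi0 * fdr_qvalues(p), 1.0)


def scan(table: GenotypeTable, families: FamilySet, config: ScanConfig = ScanConfig(),
         metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit the transmission model at every SNP of a recoded, filtered table.

    Returns one row per SNP with estimates, test fields and QC metrics
    (columns ``RESULT_COLUMNS``).  SNPs where alpha is not estimable (no
    informative families) keep NaN test fields and are excluded from the
    FDR correction.
    """
    from .qc import snp_metrics

    if table.n_snps == 0:
        logger.warning("empty SNP set: nothing to scan")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if metrics is None:
        metrics = snp_metrics(table, families)
    metrics = metrics.set_index("snp_id")
    fams = families.resolve(table)

    rows = []
    n_nonestimable = 0
    for j in range(table.n_snps):
        snp_id = table.snp_ids[j]
        counts = tabulate(table.genotypes[j], fams)
        full = fit_full(counts)
        null = fit_null(counts)
        stat, p = lrt_pvalue(full, null)
        if not full.estimable:
            n_nonestimable += 1
        met = metrics.loc[snp_id]
        rows.append({
            "snp_id": snp_id,
            "chrom": table.chrom[j],
            "pos": int(table.pos[j]),
            "alpha": full.alpha,
            "pi_E": full.pi_e,
            "pi_R": full.pi_r,
            "lnL_full": full.lnl,
            "lnL_null": null.lnl,
            "lrt": stat,
            "p_value": p,
            "q_value": np.nan,
            "call_rate": met["call_rate"],
            "consistency": met["consistency"],
            "maf": met["maf"],
            "dam_het": met["dam_het"],
            "n_families_used": counts.total,
        })
    if n_nonestimable:
        logger.warning("%d SNP(s) non-estimable (no informative families)", n_nonestimable)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = results["p_value"].notna()
    if tested.any():
        qfun = fdr_qvalues if config.fdr_method == "bh" else storey_qvalues
        results.loc[tested, "q_value"] = qfun(results.loc[tested, "p_value"].to_numpy())
    return results


def run_scan(
    table: GenotypeTable, families: FamilySet, config: ScanConfig = ScanConfig()
) -> tuple[pd.DataFrame, FilterReport]:
    """Full pipeline: major-allele recode -> QC cascade -> per-SNP scan."""
    logger.info("loaded %d SNPs x %d individuals, %d families",
                table.n_snps, table.n_individuals, len(families))
    table = recode_major_allele(table)
    filtered, report = apply_filters(table, families, config.filters)
    for stage, rem, ret in zip(report.stages, report.removed, report.retained):
        logger.info("filter %-12s removed %6d, retained %6d", stage, rem, ret)
    kept = set(filtered.snp_ids)
    metrics = report.metrics[report.metrics["snp_id"].isin(kept)].reset_index(drop=True)
    results = scan(filtered, families, config, metrics=metrics)
    n_sig = int((results["q_value"] < config.fdr_level).sum())
    logger.info("scan complete: %d SNPs tested, %d significant at q < %g",
                int(results["p_value"].notna().sum()), n_sig, config.fdr_level)
    return results, report


def write_results(results: pd.DataFrame, path) -> dict:
    """Write the results TSV (floats at 6 significant digits) and return a
    summary: significant-SNP count at q < 0.05 and the fraction negative."""
    out = results.copy()
    float_cols = [c for c in RESULT_COLUMNS if c not in
                  ("snp_id", "chrom", "pos", "n_families_used")]
    for c in float_cols:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
    return summarize(results)


def summarize(results: pd.DataFrame, fdr_level: float = 0.05) -> dict:
    sig = results[results["q_value"] < fdr_level]
    n_sig = len(sig)
    frac_neg = float((sig["alpha"] < 0).sum() / n_sig) if n_sig else float("nan")
    return {
        "n_snps": len(results),
        "n_tested": int(results["p_value"].notna().sum()),
        "n_significant": n_sig,
        "fraction_negative": frac_neg,
    }


def manhattan_table(results: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Top hit (smallest q, ties to smaller position) per chromosome at
    q below ``fdr_level``; chromosomes with no significant SNP are absent."""
    sig = results[results["q_value"] < fdr_level]
    if sig.empty:
        return sig.copy()
    sig = sig.sort_values(["q_value", "pos"], kind="mergesort")
    return sig.groupby("chrom", sort=False).head(1).reset_index(drop=True)


def manhattan_plot(results: pd.DataFrame, path, fdr_level: float = 0.05) -> None:
    """Optional convenience: -log10(q) by genome position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tested = results[results["q_value"].notna()].copy()
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for k, (chrom, grp) in enumerate(tested.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(np.maximum(grp["q_value"], 1e-300)),
                   s=6, color=["#444444", "#999999"][k % 2])
        offset = x.max() if len(x) else offset
    ax.axhline(-np.log10(fdr_level), color="red", lw=0.8)
    ax.set_xlabel("genome position")
    ax.set_ylabel("-log10 q")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
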