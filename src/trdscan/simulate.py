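"""Forward simulator for dam-offspring SNP panels with known distortion.

Runs the transmission model forward: dams are drawn from Hardy-Weinberg
proportions at a per-SNP allele frequency, each dam transmits allele A1
with probability 1 / 0.5+alpha / 0 according to her genotype, and the
ungenotyped sire contributes A1 with the frequency pi of his variety.
Sire genotypes are never materialized — only the transmitted paternal
allele matters to the likelihood.  Per-call missingness is applied
independently.

Default family numbers follow a two-variety design with 97 E-sired and 32
R-sired families for an Entrepelado-dam panel (use ``dam_variety="R"`` for
the 57/61 Retinto-dam panel).  One offspring per dam.

All draws come from one seeded numpy Generator, consumed in a fixed order
(dam genotypes, then per-SNP maternal transmissions, paternal alleles and
missingness masks), so output is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .family_data import MISSING, FamilyRecord, FamilySet, GenotypeTable
from .likelihood import ALPHA_BOUND, fit_full, fit_null, lrt_pvalue, tabulate

__all__ = ["SimConfig", "SimTruth", "simulate", "write_plink", "write_family_tsv",
           "null_calibration", "power_curve"]

_CROSS_DEFAULTS = {"E": (97, 32), "R": (57, 61)}  # (E-sired, R-sired) per dam variety


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; scalars broadcast over SNPs, arrays are per-SNP.

    ``dam_allele_freq``, ``pi_e``, ``pi_r`` default to None, meaning each
    SNP's value is drawn once from Uniform(0.1, 0.9) — a panel of common
    variants as left by a MAF filter.  ``alpha`` defaults to 0 (no
    distortion).  ``missing_rate`` is per-call.
    """

    n_snps: int = 100
    dam_variety: str = "E"
    n_families_e: int | None = None  # E-sired families; None -> design default
    n_families_r: int | None = None
    dam_allele_freq: float | np.ndarray | None = None
    pi_e: float | np.ndarray | None = None
    pi_r: float | np.ndarray | None = None
    alpha: float | np.ndarray = 0.0
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dam_variety not in _CROSS_DEFAULTS:
            raise ValueError("dam_variety must be 'E' or 'R'")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        for name in ("dam_allele_freq", "pi_e", "pi_r"):
            v = getattr(self, name)
            if v is not None and np.any((np.asarray(v) < 0) | (np.asarray(v) > 1)):
                raise ValueError(f"{name} must lie in [0,1]")
        if np.any(np.abs(np.asarray(self.alpha)) > ALPHA_BOUND):
            raise ValueError(f"alpha must lie in [-{ALPHA_BOUND}, {ALPHA_BOUND}]")
        a = self.cross_counts()
        if a[0] < 0 or a[1] < 0:
            raise ValueError("family counts must be >= 0")

    def cross_counts(self) -> tuple[int, int]:
        d_e, d_r = _CROSS_DEFAULTS[self.dam_variety]
        return (
            d_e if self.n_families_e is None else self.n_families_e,
            d_r if self.n_families_r is None else self.n_families_r,
        )

    def scaled_to(self, n_families: int) -> "SimConfig":
        """Same E:R sire mix rescaled to ``n_families`` total."""
        e, r = self.cross_counts()
        n_e = round(n_families * e / (e + r))
        return replace(self, n_families_e=n_e, n_families_r=n_families - n_e)


@dataclass
class SimTruth:
    """Ground truth: per-SNP parameters and per-family latent transmissions."""

    dam_allele_freq: np.ndarray
    alpha: np.ndarray
    pi_e: np.ndarray
    pi_r: np.ndarray
    maternal_a1: np.ndarray  # (n_snps, n_families) bool: dam transmitted A1
    paternal_a1: np.ndarray  # (n_snps, n_families) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dam_allele_freq": self.dam_allele_freq,
                "alpha": self.alpha,
                "pi_e": self.pi_e,
                "pi_r": self.pi_r,
            }
        )


def _per_snp(value, default_draw, n_snps: int, rng) -> np.ndarray:
    if value is None:
        return default_draw(rng, n_snps)
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_snps,))
    return arr.copy()


def simulate(config: SimConfig) -> tuple[GenotypeTable, FamilySet, SimTruth]:
    """Draw a full dam-offspring panel under the transmission model.

    Alleles are emitted as 'A' (the simulated A1, whose dam frequency is
    ``dam_allele_freq``) and 'B', so downstream major-allele recoding may
    or may not flip a SNP depending on the realized pooled frequency.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    n_e, n_r = config.cross_counts()
    n_fam = n_e + n_r
    if n_fam == 0:
        raise ValueError("at least one family required")

    udraw = lambda r, k: r.uniform(0.1, 0.9, size=k)
    freq = _per_snp(config.dam_allele_freq, udraw, m, rng)
    pi_e = _per_snp(config.pi_e, udraw, m, rng)
    pi_r = _per_snp(config.pi_r, udraw, m, rng)
    alpha = np.broadcast_to(np.asarray(config.alpha, dtype=float), (m,)).copy()

    # dam genotypes ~ HWE: Binomial(2, freq) per SNP x dam
    dam_geno = rng.binomial(2, freq[:, None], size=(m, n_fam)).astype(np.int8)

    # maternal transmission: P(A1) = 1, 0.5+alpha, 0 by dam genotype
    p_mat = np.select(
        [dam_geno == 2, dam_geno == 1], [1.0, (0.5 + alpha)[:, None] * np.ones((m, n_fam))], 0.0
    )
    maternal = rng.random((m, n_fam)) < p_mat

    sire_is_e = np.zeros(n_fam, dtype=bool)
    sire_is_e[:n_e] = True
    p_pat = np.where(sire_is_e[None, :], pi_e[:, None], pi_r[:, None])
    paternal = rng.random((m, n_fam)) < p_pat

    off_geno = (maternal.astype(np.int8) + paternal.astype(np.int8))

    genotypes = np.concatenate([dam_geno, off_geno], axis=1)
    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(miss, np.int8(MISSING), genotypes)

    dam_ids = np.array([f"dam{i:04d}" for i in range(n_fam)], dtype=object)
    off_ids = np.array([f"off{i:04d}" for i in range(n_fam)], dtype=object)
    alleles = np.empty((m, 2), dtype=object)
    alleles[:, 0], alleles[:, 1] = "A", "B"
    table = GenotypeTable(
        snp_ids=np.array([f"snp{j:05d}" for j in range(m)], dtype=object),
        chrom=np.array([str(1 + j % 18) for j in range(m)], dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        alleles=alleles,
        genotypes=genotypes.astype(np.int8),
        individual_ids=np.concatenate([dam_ids, off_ids]),
    )
    families = FamilySet(
        records=[
            FamilyRecord(off_ids[i], dam_ids[i], "E" if sire_is_e[i] else "R")
            for i in range(n_fam)
        ],
        dam_variety=config.dam_variety,
    )
    truth = SimTruth(freq, alpha, pi_e, pi_r, maternal, paternal)
    return table, families, truth


def write_plink(table: GenotypeTable, ped_path, map_path) -> None:
    """Write the table as PLINK text .ped/.map (allele '0' = missing)."""
    with open(map_path, "w") as fh:
        for j in range(table.n_snps):
            fh.write(f"{table.chrom[j]}\t{table.snp_ids[j]}\t0\t{table.pos[j]}\n")
    code_to_pair = {}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(table.individual_ids):
            cols = [str(iid), str(iid), "0", "0", "0", "0"]
            for j in range(table.n_snps):
                c = table.genotypes[j, i]
                a1, a2 = table.alleles[j]
                if c == MISSING:
                    cols += ["0", "0"]
                elif c == 2:
                    cols += [a1, a1]
                elif c == 1:
                    cols += [a1, a2]
                else:
                    cols += [a2, a2]
            fh.write("\t".join(cols) + "\n")


def write_family_tsv(families: FamilySet, path) -> None:
    with open(path, "w") as fh:
        fh.write("offspring_id\tdam_id\tsire_variety\n")
        for rec in families:
            fh.write(f"{rec.offspring_id}\t{rec.dam_id}\t{rec.sire_variety}\n")


def _fit_snp_pvalues(table: GenotypeTable, families: FamilySet) -> np.ndarray:
    """Per-SNP LRT p-values fitted in the table's native allele orientation."""
    fams = families.resolve(table)
    pvals = np.full(table.n_snps, np.nan)
    for j in range(table.n_snps):
        counts = tabulate(table.genotypes[j], fams)
        if counts.n_het_dam == 0:
            continue
        full = fit_full(counts)
        null = fit_null(counts)
        _, p = lrt_pvalue(full, null)
        pvals[j] = p
    return pvals


def null_calibration(
    n_snps: int, n_families: int, seed: int, missing_rate: float = 0.03
) -> dict:
    """Empirical type-I error of the LRT at p < 0.05 on null (alpha=0) SNPs.

    Simulates ``n_snps`` independent null SNPs with the default sire mix
    scaled to ``n_families``, fits each and reports the rejection fraction
    with a 95% binomial (Wilson) confidence interval, plus the count of
    Benjamini-Hochberg q < 0.05 discoveries over the whole scan.
    """
    from statsmodels.stats.proportion import proportion_confint

    from .pipeline import fdr_qvalues

    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    config = SimConfig(
        n_snps=n_snps, alpha=0.0, missing_rate=missing_rate, seed=seed
    ).scaled_to(n_families)
    table, families, _ = simulate(config)
    pvals = _fit_snp_pvalues(table, families)
    valid = pvals[~np.isnan(pvals)]
    n_valid = valid.size
    rej = int((valid < 0.05).sum())
    lo, hi = proportion_confint(rej, n_valid, alpha=0.05, method="wilson")
    q = fdr_qvalues(valid)
    result = {
        "n_snps_tested": n_valid,
        "type_i_error": rej / n_valid,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_bh_discoveries": int((q < 0.05).sum()),
        "low_information": n_families < 25,
    }
    return result


def power_curve(
    alpha_grid, n_grid, reps: int, seed: int, n_null_snps: int = 30
) -> pd.DataFrame:
    """Empirical power to detect one distorted SNP inside a small null scan.

    For each (alpha, n_families) cell, simulates ``reps`` scans of
    ``n_null_snps`` null SNPs plus one SNP distorted at ``alpha`` and
    reports the fraction of reps where that SNP reaches BH q < 0.05.
    """
    from .pipeline import fdr_qvalues

    alpha_grid = list(alpha_grid)
    n_grid = list(n_grid)
    if not alpha_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    rng = np.random.default_rng(seed)
    for a in alpha_grid:
        for n_fam in n_grid:
            hits = 0
            for _ in range(reps):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                alphas = np.zeros(n_null_snps + 1)
                alphas[0] = a
                cfg = SimConfig(
                    n_snps=n_null_snps + 1,
                    alpha=alphas,
                    dam_allele_freq=0.5,
                    seed=rep_seed,
                ).scaled_to(n_fam)
                table, families, _ = simulate(cfg)
                pvals = _fit_snp_pvalues(table, families)
                mask = ~np.isnan(pvals)
                q = np.full_like(pvals, np.nan)
                q[mask] = fdr_qvalues(pvals[mask])
                if not np.isnan(q[0]) and q[0] < 0.05:
                    hits += 1
            rows.append({"alpha": a, "n_families": n_fam, "power": hits / reps})
    return pd.DataFrame(rows)
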