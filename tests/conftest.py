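import numpy as np
import pytest

from trdscan import FamilyRecord, FamilySet, GenotypeTable
from trdscan.family_data import MISSING

_ = MISSING  # -1


def make_table(genotypes, snp_ids=None, alleles=None, individual_ids=None,
               chrom=None, pos=None):
    """Small GenotypeTable builder with sensible defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    m, n = g.shape
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(n)]
    if alleles is None:
        alleles = np.array([["A", "B"]] * m, dtype=object)
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return GenotypeTable(snp_ids, chrom, pos, alleles, g, individual_ids)


@pytest.fixture
def six_snp_panel():
    """Hand-built 6-SNP, 5-family panel: two SNPs survive the QC cascade and
    one SNP fails at each stage (pre-filter, consistency, MAF, dam het).

    Columns 0-4 are dams d0..d4, columns 5-9 their offspring o0..o4.
    Boundary cases are exact: fail_maf has MAF exactly 0.05 and
    fail_damhet has dam heterozygosity exactly 0.20 (strict > removes both).
    """
    g = [
        # d0  d1  d2  d3  d4   o0  o1  o2  o3  o4
        [1,  1,  0,  2,  1,   1,  2,  0,  1,  2],   # ok1
        [1,  0,  1,  1,  2,   0,  0,  2,  2,  2],   # ok2
        [_,  _,  _,  _,  _,   _,  _,  _,  _,  _],   # fail_pre (call rate 0)
        [1,  2,  1,  1,  1,   _,  0,  1,  1,  2],   # fail_cons (3/5 consistent)
        [1,  2,  2,  2,  2,   2,  2,  2,  2,  2],   # fail_maf (MAF = 0.05)
        [1,  0,  0,  2,  2,   1,  0,  1,  2,  2],   # fail_damhet (het = 0.20)
    ]
    ids = ["ok1", "ok2", "fail_pre", "fail_cons", "fail_maf", "fail_damhet"]
    dams = [f"d{i}" for i in range(5)]
    offs = [f"o{i}" for i in range(5)]
    table = make_table(g, snp_ids=ids, individual_ids=dams + offs)
    families = FamilySet(
        records=[FamilyRecord(f"o{i}", f"d{i}", "E" if i < 3 else "R")
                 for i in range(5)]
    )
    return table, families


@pytest.fixture(scope="session")
def null_lrt_stats():
    """LRT statistics and p-values for 2000 simulated null SNPs
    (alpha = 0, 250 families, default sire mix, fixed seed).

    Session-scoped: shared by the calibration and distribution tests.
    """
    from trdscan import SimConfig, simulate
    from trdscan.likelihood import fit_full, fit_null, lrt_pvalue, tabulate

    cfg = SimConfig(n_snps=2000, alpha=0.0, seed=20260930 % 2**31).scaled_to(250)
    table, families, _ = simulate(cfg)
    fams = families.resolve(table)
    stats, pvals = [], []
    for j in range(table.n_snps):
        counts = tabulate(table.genotypes[j], fams)
        if counts.n_het_dam == 0:
            continue
        s, p = lrt_pvalue(fit_full(counts), fit_null(counts))
        stats.append(s)
        pvals.append(p)
    return np.asarray(stats), np.asarray(pvals)
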