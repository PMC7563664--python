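"""Genotype and family-structure containers plus readers for PLINK text and VCF.

Genotypes are stored as A1-allele dosage codes in {0, 1, 2} with -1 for
missing.  After :func:`recode_major_allele`, A1 is the major allele at every
SNP (pooled over all loaded individuals), so a positive distortion estimate
always means excess transmission of the major allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "FamilyRecord",
    "FamilySet",
    "FormatError",
    "MarkerError",
    "ValidationError",
    "read_plink",
    "read_vcf",
    "read_families",
    "recode_major_allele",
]


class FormatError(ValueError):
    """Malformed input file (row/line level)."""


class MarkerError(ValueError):
    """A marker violates the biallelic-SNP contract."""


class ValidationError(ValueError):
    """Family file fails its consistency checks."""


@dataclass
class GenotypeTable:
    """SNP x individual dosage matrix with marker metadata.

    Attributes
    ----------
    snp_ids : array of str, unique marker identifiers (length m).
    chrom : array of str, chromosome label per SNP.
    pos : int array, 1-based base-pair position per SNP.
    alleles : (m, 2) array of str; column 0 is the allele counted by the
        dosage codes (A1 after recoding), column 1 the other allele.  A
        placeholder "0" marks an unobserved second allele at monomorphic SNPs.
    genotypes : (m, n) int8 array of A1 dosages, -1 for missing.
    individual_ids : array of str, unique sample identifiers (length n).
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    genotypes: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise MarkerError("duplicate SNP identifiers")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual identifiers")
        g = self.genotypes
        if g.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise FormatError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.individual_ids)} individuals"
            )
        bad = (g != MISSING) & ((g < 0) | (g > 2))
        if bad.any():
            raise MarkerError("genotype codes outside {0,1,2,missing}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def index_of(self, individual_id: str) -> int:
        idx = np.flatnonzero(self.individual_ids == individual_id)
        if idx.size == 0:
            raise KeyError(individual_id)
        return int(idx[0])

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            alleles=self.alleles[mask],
            genotypes=self.genotypes[mask],
            individual_ids=self.individual_ids,
        )


@dataclass(frozen=True)
class FamilyRecord:
    offspring_id: str
    dam_id: str
    sire_variety: str  # "E" or "R"


@dataclass
class FamilySet:
    """Offspring->dam links with the sire's source population label.

    One record per offspring; analyses are run per dam variety, so the
    optional ``dam_variety`` labels the whole set.
    """

    records: list[FamilyRecord] = field(default_factory=list)
    dam_variety: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sire_variety not in ("E", "R"):
                raise ValidationError(
                    f"sire_variety must be 'E' or 'R', got {rec.sire_variety!r} "
                    f"for offspring {rec.offspring_id!r}"
                )
            if rec.offspring_id in seen:
                raise ValidationError(f"offspring {rec.offspring_id!r} appears twice")
            seen.add(rec.offspring_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sire_counts(self) -> dict[str, int]:
        counts = {"E": 0, "R": 0}
        for rec in self.records:
            counts[rec.sire_variety] += 1
        return counts

    def resolve(self, table: GenotypeTable) -> list[tuple[int, int, str]]:
        """Map each family to (offspring column, dam column, sire variety).

        Families whose offspring or dam is absent from the table are dropped
        with a warning; the model needs both genotypes.
        """
        col = {iid: i for i, iid in enumerate(table.individual_ids)}
        out = []
        n_dropped = 0
        for rec in self.records:
            if rec.offspring_id in col and rec.dam_id in col:
                out.append((col[rec.offspring_id], col[rec.dam_id], rec.sire_variety))
            else:
                n_dropped += 1
        if n_dropped:
            warnings.warn(
                f"{n_dropped} families dropped: member(s) not genotyped", stacklevel=2
            )
        return out


def read_plink(ped_path, map_path) -> GenotypeTable:
    """Read whitespace-delimited PLINK text .ped/.map files.

    The returned table codes each genotype as the dosage of the first allele
    seen at that SNP (file order); call :func:`recode_major_allele` to put
    every SNP on the major-allele orientation.  Allele "0" is missing; a pair
    with one "0" is treated as wholly missing (PLINK convention).
    """
    snp_ids, chrom, pos = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            pos.append(int(parts[3]))
    m = len(snp_ids)

    individual_ids: list[str] = []
    pairs: list[list[tuple[str, str]]] = []  # per individual, per SNP
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2x{m} alleles), got {len(parts)}"
                )
            individual_ids.append(parts[1])
            row = parts[6:]
            pairs.append([(row[2 * j], row[2 * j + 1]) for j in range(m)])

    n = len(individual_ids)
    genotypes = np.full((m, n), MISSING, dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    for j in range(m):
        a1: str | None = None
        a2: str | None = None
        for i in range(n):
            x, y = pairs[i][j]
            if x == "0" or y == "0":
                continue  # single "0" voids the whole call
            for a in (x, y):
                if a1 is None:
                    a1 = a
                elif a != a1 and a2 is None:
                    a2 = a
                elif a != a1 and a != a2:
                    raise MarkerError(
                        f"SNP {snp_ids[j]!r}: >2 distinct alleles ({a1}, {a2}, {a})"
                    )
            genotypes[j, i] = (x == a1) + (y == a1)
        alleles[j, 0] = a1 if a1 is not None else "0"
        alleles[j, 1] = a2 if a2 is not None else "0"
    return GenotypeTable(snp_ids, chrom, pos, alleles, genotypes, individual_ids)


def read_vcf(vcf_path) -> GenotypeTable:
    """Read biallelic SNP records from a VCF 4.x file (gzip-transparent).

    Dosage counts the REF allele (recode afterwards); ``./.`` is missing.
    Multi-allelic records are skipped with a warning reporting the count.
    """
    import pysam

    snp_ids, chrom, pos, alleles, rows = [], [], [], [], []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                row[i] = sum(1 for a in gt if a == 0)  # REF dosage
            snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            chrom.append(str(rec.chrom))
            pos.append(rec.pos)
            alleles.append((rec.ref, rec.alts[0]))
            rows.append(row)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic record(s)", stacklevel=2)
    m = len(snp_ids)
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    allele_arr = np.empty((m, 2), dtype=object)
    for j, (a, b) in enumerate(alleles):
        allele_arr[j, 0], allele_arr[j, 1] = a, b
    return GenotypeTable(snp_ids, chrom, pos, allele_arr, genotypes, samples)


def read_families(tsv_path, dam_variety: str | None = None) -> FamilySet:
    """Read the 3-column family TSV: offspring_id, dam_id, sire_variety."""
    records = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["offspring_id", "dam_id", "sire_variety"]
        if [h.strip() for h in header[:3]] != expected:
            raise ValidationError(
                f"{tsv_path}: header must start with {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{tsv_path}:{lineno}: expected 3 columns")
            off, dam, sire = (p.strip() for p in parts[:3])
            if sire not in ("E", "R"):
                raise ValidationError(
                    f"{tsv_path}:{lineno}: sire_variety must be E or R, got {sire!r}"
                )
            records.append(FamilyRecord(off, dam, sire))
    return FamilySet(records=records, dam_variety=dam_variety)


def recode_major_allele(table: GenotypeTable) -> GenotypeTable:
    """Re-orient every SNP so that A1 is the major allele.

    The major allele is determined by pooled counts over all non-missing
    calls of all individuals in the table.  Where the orientation flips,
    code c becomes 2 - c and the allele labels swap.  Ties at 0.5/0.5 give
    A1 to the lexicographically smaller label.  Idempotent.
    """
    g = table.genotypes
    nonmiss = g != MISSING
    n_calls = nonmiss.sum(axis=1)
    a1_count = np.where(nonmiss, g, 0).sum(axis=1)  # copies of current A1
    a2_count = 2 * n_calls - a1_count

    new_g = g.copy()
    new_alleles = table.alleles.copy()
    for j in range(table.n_snps):
        a1, a2 = table.alleles[j]
        if a2 == "0":  # monomorphic: observed allele is A1, codes already 2
            continue
        flip = a2_count[j] > a1_count[j]
        if a1_count[j] == a2_count[j]:
            flip = str(a2) < str(a1)
        if flip:
            row = new_g[j]
            keep = row != MISSING
            row[keep] = 2 - row[keep]
            new_alleles[j, 0], new_alleles[j, 1] = a2, a1
    return replace(table, genotypes=new_g, alleles=new_alleles)
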