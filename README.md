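# trdscan

Genome scan for **maternal transmission ratio distortion (TRD)** in
dam–offspring SNP panels with **ungenotyped sires** from two source
populations.

TRD is the deviation of allele transmission from a heterozygous parent
away from the Mendelian 1:1 expectation — caused by meiotic drive,
gamete competition, or early-lethal genotypes. Family designs common in
livestock (genotyped dams and daughters; valuable sires never sampled)
rule out classical transmission tests that need both parental genotypes.
`trdscan` implements a per-SNP multinomial likelihood in which the
offspring genotype combines

- a **maternal allele**: the major allele A1 transmitted with probability
  1, 0.5 + α, or 0 by A1A1, A1A2, and A2A2 dams respectively — α ∈
  (−0.5, 0.5) is the maternal distortion parameter, 0 under Mendelian
  segregation; and
- a **paternal allele**: A1 with probability π_E or π_R, the unknown A1
  frequency among the sires of each variety, estimated per SNP as
  nuisance parameters that absorb any paternal effects.

(α, π_E, π_R) are estimated by constrained maximum likelihood (gradient
ascent on reparameterized coordinates with an exact α-profile polish),
α = 0 is tested with a likelihood ratio test against χ²₁, and the scan is
corrected with Benjamini–Hochberg q-values (FDR 0.05). A QC cascade
keeps only informative markers: family consistency rate > 75%, minor
allele frequency > 5%, dam heterozygosity > 20% (only heterozygous dams
inform α). A seeded forward simulator generates complete panels with
known (α, π_E, π_R), the two-variety cross design (97 + 32 E-dam
families, 57 + 61 R-dam families by default), and per-call missingness,
so every stage is testable without external data. See
[docs/methods.md](docs/methods.md) for the model details and numerics.

## Worked example

`examples/run_scan.py` simulates a 200-SNP, 250-family panel with three
planted TRD loci (α = −0.4, −0.3, +0.35), writes it to PLINK text files,
runs the full pipeline and prints:

```
filter cascade:
      stage  removed  retained
 pre_filter        0       200
consistency        0       200
        maf        0       200
    dam_het        4       196

summary: {'n_snps': 196, 'n_tested': 196, 'n_significant': 3, 'fraction_negative': 0.3333333333333333}

top hit per chromosome (q < 0.05):
  snp_id chrom    pos     alpha      p_value      q_value  dam_het
snp00060     7  61000  0.422224 1.537362e-12 3.013229e-10 0.500000
snp00010    11  11000  0.321324 1.314412e-05 1.288124e-03 0.414938
snp00110     3 111000 -0.264322 1.312101e-04 8.572396e-03 0.470833
```

All three planted loci — and nothing else — pass q < 0.05. `alpha` is
the estimated shift of the heterozygous dams' A1-transmission
probability (0.5 + α); its sign is relative to the recoded major allele,
so a strong planted distortion that drags the pooled allele frequency
past 1/2 reports with flipped sign. Other examples:
`examples/fit_one_snp.py` (single-SNP fit against known truth) and
`examples/power_study.py` (type-I error and power tables).

## Command line

```sh
trdscan --geno panel.ped --map panel.map --fam families.tsv \
        --min-maf 0.05 --min-consistency 0.75 --min-dam-het 0.20 \
        --fdr 0.05 --out scan --seed 1
```

reads PLINK text `.ped/.map` or VCF genotypes plus a three-column family
TSV (`offspring_id`, `dam_id`, `sire_variety` ∈ {E, R}) and writes
`scan.results.tsv` (per-SNP estimates, LRT p- and q-values, QC metrics),
`scan.filter_report.tsv` and `scan.log`. Identical inputs and seed give
byte-identical outputs.

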