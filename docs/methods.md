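# Methods

`trdscan` detects maternal transmission ratio distortion (TRD) — deviation
of allele transmission from heterozygous dams to their offspring away from
the Mendelian 1:1 expectation — in SNP panels where each family consists of
a genotyped dam, one genotyped offspring, and an ungenotyped sire drawn
from one of two source populations (labelled E and R).

## Model

At a biallelic SNP with alleles A1/A2 (A1 = major allele after recoding),
the offspring genotype is the sum of one maternal and one paternal allele.
The dam transmits A1 with probability

| dam genotype | P(transmits A1) |
|---|---|
| A1A1 (code 2) | 1 |
| A1A2 (code 1) | 0.5 + α |
| A2A2 (code 0) | 0 |

and the sire contributes A1 with probability π_s, the A1 frequency among
the sires of his variety s ∈ {E, R}. Offspring genotype probabilities are

- P(A1A1) = p_dam(A1) · π_s
- P(A1A2) = p_dam(A1) · (1 − π_s) + p_dam(A2) · π_s
- P(A2A2) = p_dam(A2) · (1 − π_s)

α is the maternal distortion parameter (0 under Mendelian segregation);
the two π parameters are nuisance parameters that absorb the sires' allele
frequencies *and any paternal distortion*, so the test isolates the
maternal effect. Families are treated as independent; the per-SNP
likelihood is a multinomial over the (dam genotype × offspring genotype ×
sire variety) count table, restricted to complete, Mendelian-compatible
pairs.

Significance is a likelihood ratio test of α = 0 against the free-α fit,
referred to a χ² distribution with 1 df (only α is constrained; both π's
are free under both hypotheses, and a sire variety with no families at a
SNP drops its π from both fits without changing the df). Genome-wide
correction uses Benjamini–Hochberg q-values at the 0.05 level by default;
a Storey-type option (fixed λ = 0.5 π₀ estimate) is available but BH is
the default because π₀ estimation is unstable at the few-thousand-SNP scan
sizes the simulator produces.

## Parameter bounds and numerics

- α is bounded at ±0.495 rather than ±0.5, keeping every transmission
  probability strictly positive; SNPs with essentially complete distortion
  therefore report ±0.495. π ∈ [0, 1].
- **Fit.** Gradient ascent on reparameterized coordinates (α =
  0.495·tanh(u), π = logistic(v)) with analytic gradients, backtracking
  line search, relative-improvement stop at 1e−10 (10,000 iterations cap),
  from five deterministic start points (α ∈ {0, ±0.25, ±0.45}, π at the
  null-model estimates or 0.5). The best restart is then polished on the
  **α-profile likelihood**: each cell probability is bilinear in (α, π),
  so for fixed α the per-variety log-likelihood is concave in π and its
  maximizer is found exactly by golden section; the profile over α is
  scanned coarsely (step 0.01, vectorized) and the best point refined by
  golden section (tolerance 1e−8). The profile stage reaches boundary
  optima that the soft reparameterization only approaches asymptotically
  and escapes coordinate-locked local modes that defeat per-coordinate
  polish (these occur: some count tables have a local mode at interior α
  with a π at 1 and a global mode at boundary α). On 300 random count
  tables of ≤ 60 families the fitted log-likelihood never fell more than
  2e−9 below an exhaustive 0.001-step 3-D grid search.
- **Null fit.** With α = 0 the likelihood factorizes by sire variety and
  each π is a closed-form binomial proportion over the cells in which the
  paternal allele is observable (het-dam/het-offspring cells are
  uninformative, probability ½ regardless of π).
- Exact likelihood ties between modes are broken toward the smaller |α|.
- The LRT statistic is clipped at 0. No boundary-mixture (½χ²₀ + ½χ²₁)
  correction is applied, matching the plain test the scan is built
  around; since α = 0 is interior to the parameter space, the statistic
  is asymptotically χ²₁ anyway and clipping only absorbs numerical
  negatives. At 250 families the empirical type-I error at p < 0.05 runs
  slightly high (≈ 0.053–0.059 across seeds) — a finite-sample effect,
  not the clipping.

## Identifiability

α is informed only by heterozygous-dam families, and within those
families α and π are partially confounded: if *all* informative families
at a SNP have heterozygous dams, the null model (free π) already fits the
two homozygous offspring classes exactly and the LRT sees only the
heterozygous-offspring fraction — which at π = 0.5 carries no α signal at
all. In practice homozygous-dam families pin π and the dam-heterozygosity
QC filter (> 20%) guarantees a mix; this is also why that filter matters
beyond information content. SNPs with no heterozygous-dam families are
reported as non-estimable and excluded from the FDR correction.

## QC cascade

Strict inequalities throughout, applied in order: (1) pre-filter removing
SNPs with zero call rate or no polymorphism; (2) family consistency rate
> 0.75 — the fraction of families with both members genotyped *and*
Mendelian-compatible (opposite-homozygote dam/offspring pairs are treated
as genotyping errors: they would carry likelihood 0, so they are excluded
both from this numerator and from the count tables); (3) minor allele
frequency > 0.05 over all non-missing calls (dams + offspring); (4) dam
heterozygosity > 0.20 among non-missing dams. Each stage is a per-SNP
predicate, so the surviving set is an intersection and does not depend on
stage order — only the per-stage removal counts do. MAF is computed by
direct allele counting so boundary fractions like 1/20 compare exactly
against the 0.05 threshold.

Allele recoding makes A1 the major allele per SNP by pooled count over
all loaded individuals, with ties going to the lexicographically smaller
allele label; a code c becomes 2 − c where the orientation flips. All
reported α share one sign convention: α < 0 means the minor allele is
over-transmitted. The X chromosome is treated like an autosome, which is
valid when offspring are all female (dam→daughter transmission is
diploid, the sire contributes one X allele at frequency π); male
offspring would break this and are not modelled.

## Simulator

`trdscan.simulate` runs the model forward: dam genotypes from
Hardy–Weinberg proportions at a per-SNP allele frequency, maternal
transmission at 0.5 + α from heterozygous dams, paternal allele A1 with
probability π of the sire's variety, then independent per-call
missingness. Sire genotypes are never materialized — only the transmitted
allele matters to the likelihood. Defaults encode the two-variety study
design the tool targets: 97 E-sired + 32 R-sired families for an
E-dam panel (57/61 for an R-dam panel), one offspring per dam;
`SimConfig.scaled_to(n)` rescales the total holding that sire mix. Where
the design does not pin a value the defaults are: dam allele frequency
and both π drawn once per SNP from Uniform(0.1, 0.9) (a common-variant
panel, as left by an upstream MAF screen), α = 0, missingness 0.03 —
typical of array data that passed laboratory QC.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs (draws are independent, so genome-wide discovery counts ignore
correlated tests), genotyping error (no Mendelian-incompatible pairs are
generated; the consistency filter is exercised only by hand-built
fixtures), shared dams across families, and selection/drift structure in
the founder frequencies. Passing calibration and power results therefore
speak to the statistical machinery, not to error-contaminated real data.

## Problem sizes used in the shipped checks

Simulation-backed checks run at 2000 null SNPs × 250 families for LRT
calibration (type-I error band [0.02, 0.06] at p < 0.05; ≤ 2 BH
discoveries at q < 0.05; positive LRT part one-sided-KS-compatible with
χ²₁ at level 0.01), 200 SNPs for parameter recovery at
(α, π_E, π_R) = (−0.3, 0.6, 0.4) (mean α̂ within ±0.03, mean π̂ within
±0.05), 20 random tables against the exhaustive grid oracle, and 100
tables for the label-swap symmetry identity
lnL(n; α, π) = lnL(n reflected; −α, 1 − π) at 1e−10. These sizes give
stable Monte-Carlo estimates at interactive runtimes; the same machinery
scales linearly in SNP count.

## Known limitations

- One offspring per dam is the intended design; repeated dams are
  accepted but their families are (incorrectly) treated as independent.
- The LRT is mildly anticonservative at a few hundred families (see
  above); FDR-level conclusions at q < 0.05 were robust to this in all
  shipped calibration runs.
- Dams must be genotyped; families with missing dam or offspring calls at
  a SNP simply drop out of that SNP's count table.
- No LD-aware correction: q-values treat SNPs as exchangeable tests.
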