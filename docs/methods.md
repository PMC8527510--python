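# Methods

## Setting and data model

The package assumes two inputs for a cohort of host individuals:

1. **A dense SNP genotype matrix** for the genotyped DNA samples: calls in
   {AA, AB, BB, missing} at biallelic SNPs, with alleles coded by frequency
   in the source population (A = major, B = minor). Internally calls are
   minor-allele dosage 0/1/2 with NaN for missing. In a multiparental
   population the matrix is produced by collapsing founder-diplotype
   probabilities (from an array-genotype HMM, computed upstream) against a
   founder-strain variant table; elsewhere it can come directly from a VCF.
2. **Per-microbiome-sample allele counts**: for each SNP, the number of
   host-derived reads carrying the major and the minor allele. These can be
   tabulated from a coordinate-sorted, indexed BAM (`extract_allele_counts`,
   default minimum base quality 20, mapping-quality threshold 0 and
   configurable), but the canonical interchange format is a plain TSV so the
   statistical core is testable without alignment files.

Reads are treated as independent Bernoulli draws of an allele given the
template DNA — each aligned segment counts once per overlapped site, mates
independently, duplicates are not removed, and bases matching neither
coded allele are discarded (tallied in the log).

## Genotype preparation

- SNPs without exactly two distinct founder alleles are dropped: more than
  two alleles breaks the A/B coding; one allele carries no identity
  information; a missing founder allele leaves the diplotype→genotype map
  undefined.
- Major/minor is decided by founder-strain frequency; a 4–4 tie goes to the
  lexicographically smaller nucleotide so the coding never depends on the
  order of founder columns.
- Diplotype probabilities collapse to genotype marginals by summing the
  probabilities of founder pairs implying each dosage (founders are assumed
  fully inbred, one haploid allele each). The call is the argmax marginal
  provided it exceeds the call threshold (default **0.95**); otherwise
  missing. Raising the threshold can only turn calls missing, never flip
  them. For SNPs between array markers, the flanking markers' diplotype
  probabilities may be averaged (the probabilities are assumed constant
  within an inter-marker interval).

## Discordance distance and classification

For microbiome sample *i* and genotyped sample *j*, among reads at SNPs
where *j* is homozygous, the distance d(i, j) is the fraction carrying the
allele absent from *j*'s genotype. Heterozygous SNPs are excluded — either
allele is consistent with the genotype, so they dilute the signal (they are
retained in the category tables for the mixture model). If no reads fall at
homozygous sites the distance is undefined and propagates as missing, never
as 0.

Expected values under the read model: d ≈ ε for a correct label; for an
unrelated individual d is driven by genotype discordance (≈0.2 for the
populations simulated here). Classification thresholds (all configurable):

| parameter | default | meaning |
|---|---|---|
| `match_low` | 0.01 | below this, a genotyped sample is a clear match |
| `self_high` | 0.15 | above this, the label cannot be right |
| `mixture_gray` | 0.05 | self-closest but farther than this ⇒ suspicious |
| `low_reads_floor` | 100 000 | minimum reads overlapping SNPs to classify |

A sample is **correct** (self closest, d < `match_low`), a **swap** (self
beyond `self_high`, some other sample within `match_low`), a **mixture
candidate** (minimum distance in [`match_low`, `self_high`), or self-closest
within the gray zone), **low_reads**, or **unresolved**. The gray zone is an
explicit operationalization — visual inspection of min-vs-self distance
plots is the traditional criterion, and the candidate label only queues a
sample for the mixture scan, which makes the actual call. Low-quality DNA
samples cannot be recognized from the distance matrix alone and are
declared by the caller. Ties for the closest sample keep column order, with
a warning.

## Mixture model

A microbiome sample is modeled as a two-source mixture: proportion *p* of
its host DNA from a candidate contaminant, 1 − *p* from the labeled
individual, with symmetric per-read error ε. With f(g) ∈ {0, ½, 1} the
minor-allele frequency implied by genotype g,

    Pr(read = B | g_self, g_other) = ε + [(1−p)·f(g_self) + p·f(g_other)]·(1−2ε).

Conditional on the per-cell totals of the 3×3×2 joint table, the
18-category multinomial factorizes into nine independent binomials, which is
the implemented form (identical MLEs, simpler numerics). Binomial
coefficients are dropped consistently, so likelihood *ratios* are exact.

**Parameters.** p ∈ [0, 1] (proportion of host DNA from the contaminant,
dimensionless); ε ∈ [0, 0.5) (per-read allele error probability). Under the
null p = 0, ε's MLE has a closed form — the pooled discordant fraction at
homozygous-self rows (AB rows are free of ε) — which the 1-D numerical null
fit is checked against.

**Optimization.** The alternative is maximized on an unconstrained scale
(logit p, logit 2ε) with Nelder–Mead from five starts: moment estimates
(the discordant fraction in the (AA,BB)/(BB,AA) cells estimates
ε + p(1−2ε) ≈ p; the null ε̂₀ seeds ε), a low-contamination start
(0.01, 0.005), and near-boundary starts p ≈ 0, 0.5, 0.99. The best result
is kept; if it falls below the null likelihood the null is reported
(guaranteeing LRT ≥ 0, with a −10⁻⁶ numerical floor clipped to 0). Fits
agree with an exhaustive two-stage grid search to |Δp̂| < 2×10⁻³. If no
reads fall in a cell where the two genotypes imply different allele
frequencies, p is unidentifiable; the fit is returned flagged with p̂ = 0
and LRT = 0 rather than dropped.

**Scan and separation rule.** Every other genotyped sample is fit as the
candidate contaminant. Because the binomial model ignores overdispersion,
at realistic depths the LRT is nominally significant for essentially every
candidate on real data; contaminants are therefore called by *separation*:
with L1 ≥ L2 the two largest LRTs, the top candidate is flagged iff
L1/L2 ≥ `gap_factor` (default **10**) and L1 exceeds a minimum-evidence
floor. The floor defaults to the Bonferroni-adjusted 5% critical value of
the boundary-null LRT distribution (½δ₀ + ½χ²₁) over the scan's candidates
— `run_study` widens the adjustment to all fits in the cohort — and exists
because an otherwise-null scan can produce a single small positive LRT over
near-zero competitors, which a bare ratio would misread as separation. On
real data, where observed LRTs start in the hundreds, the floor never
binds. No other multiple-testing correction is applied.

`run_study` scans every sample by default in cohorts of ≤ 500 genotyped
samples (configurable): mixtures with small p can look perfectly correct in
the distance analysis and are only caught by the scan. Verdict precedence
is swap > mixture > low_reads — a swapped sample also triggers the scan
(p̂ ≈ 1 against its true source) but is reported as a swap.

## Synthetic cohorts

`mbmixups.simulate` generates both inputs under the same read model the
mixture analysis fits, so every downstream module is testable end to end:

- per-SNP minor-allele frequency ~ Uniform(0.05, 0.5) by default;
- genotypes ~ Binomial(2, MAF) per sample (Hardy–Weinberg). The identity
  and mixture statistics depend only on genotype frequencies and read
  counts, not on pedigree, so the founder-mosaic structure of a
  multiparental population is not emulated (the diplotype-collapse path is
  tested separately with hand-built probability fixtures);
- per-SNP read totals ~ Poisson(depth), with a per-sample depth multiplier
  drawn log-uniform over [0.1, 10] emulating the order-of-magnitude
  variation in host-read fraction across real fecal libraries (default
  mean: 50 reads/SNP × 2000 SNPs ≈ 10⁵ host reads per sample);
- minor-read counts ~ Binomial(total, ε + f*(1−2ε)) with f* set by the
  scenario (correct label, swap, or mixture at a given p); ε defaults
  to 0.005;
- a mandatory seed makes cohorts byte-identical across runs.

Features of real data *not* emulated: linkage disequilibrium between SNPs,
relatedness between cohort members, overdispersion of read counts
(PCR/duplicate structure), reference-mapping bias toward the major allele,
and genotype-imputation errors. Passing tests therefore demonstrate the
estimators' behavior under the model's own assumptions, not robustness to
those artifacts; on real data the LRT's null calibration in particular is
known to be optimistic, which is exactly why detection relies on the
separation heuristic.

Test and acceptance studies use scaled-down problem sizes chosen to keep
the method in its intended operating regime: panels of 2 000–10 000 SNPs
and 10⁵–10⁶ reads per sample (real studies: millions of informative sites).
Panel size matters for the scan — the chance-alignment component of a wrong
candidate's LRT scales with reads-per-SNP, so very small panels compress
the separation ratio; below roughly 5 000 SNPs at 10⁶ reads the scan leaves
the regime the method was designed for.

## Known limitations

- **Separation margin.** Even with many SNPs, a wrong candidate's LRT is an
  intrinsic fraction (~8–10% in the simulated populations) of the true
  contaminant's: the wrong-candidate fit repairs the null's coupled
  intercept/slope constraint via its free p, and shared allele frequencies
  correlate any two samples' genotypes. The true contaminant reliably
  attains the *maximum* LRT, but its separation ratio sits near 10–13, so
  the default `gap_factor` = 10 is a thin margin and borderline scans
  deserve a look at the LRT-vs-p̂ plot, which is what the rule
  operationalizes.
- Two sources only: three-way mixtures are not modeled (the scan will
  typically surface one of the sources).
- The symmetric single-ε error model ignores allele-specific and
  site-specific error; samples with atypical error profiles inflate ε̂.
- A swap is detected as such, but whether the genomic DNA or the microbiome
  aliquot was swapped cannot be decided from these data alone.
- Autosomal SNPs are the intended input; X-chromosome dosage is not
  handled.
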