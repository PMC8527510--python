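# mbmixups

Detection of **sample mix-ups** and **sample mixtures** in shotgun-metagenome
cohorts, using the host-derived fraction of the sequence reads.

## The problem

Shotgun sequencing of fecal (or other host-associated) DNA yields mostly
microbial reads, but a variable fraction — often several percent to a quarter
of the library — maps to the host genome. When dense SNP genotypes are also
available for the host individuals (for example, imputed from a genotyping
array plus a founder-strain variant database in a multiparental mouse
population), those host reads fingerprint the individual. That makes two
classes of labeling error detectable *from the microbiome data themselves*:

- a **mix-up**: the microbiome sample belongs entirely to a different
  individual than its label says (a swap somewhere in the pipeline);
- a **mixture**: one microbiome sample contains host DNA from two
  individuals (contamination), in some proportion *p*.

Both errors corrupt downstream host-genetics analyses of the microbiome
(e.g., QTL mapping of microbial abundances), so screening for them is a
routine QC step this package automates.

## The statistics

Code each biallelic SNP's alleles as A (major among the founders/population)
and B (minor), and let a sample's genotype at a SNP be AA, AB or BB.

**Discordance distance (mix-ups).** For a microbiome sample and a genotyped
sample, count reads overlapping SNPs where the genotyped sample is
homozygous. The distance is the proportion of those reads carrying the
allele absent from the genotype:

    d = [n(AA,B) + n(BB,A)] / [n(AA,A) + n(AA,B) + n(BB,A) + n(BB,B)]

Under a correct label, d ≈ the sequencing error rate ε (well below 0.01);
against an unrelated individual, d is large (≈0.2). A sample whose own
column is distant (> 0.15) while another sample is near (< 0.01) is a swap.

**Binomial mixture model (mixtures).** Split the read counts by the *joint*
genotypes of the labeled sample and a candidate contaminant (9 cells × 2
alleles). With f(g) ∈ {0, ½, 1} the minor-allele frequency of genotype g,
a read carries the B allele with probability

    Pr(B) = ε + f*·(1 − 2ε),   f* = (1 − p)·f(g_self) + p·f(g_other)

where p is the contaminant proportion and ε the sequencing error rate.
Conditional on the cell totals this is nine independent binomials; (p̂, ε̂)
are maximum-likelihood estimates, and the evidence for contamination is the
likelihood-ratio statistic LRT = 2(ℓ(p̂, ε̂) − ℓ(0, ε̂₀)). Each sample is
scanned against every other genotyped sample as the candidate contaminant;
a contaminant is called when its LRT **separates** from all other
candidates' (by a factor ≥ 10 by default), not by LRT calibration — with
millions of reads the LRT is nominally significant almost everywhere.

## Worked example

Simulate an 8-sample cohort (4000 SNPs, ~200k host reads per sample) with a
planted swap pair (S002↔S005) and a 30% contamination of S007 by S003, then
run the full analysis:

```
mbmixups simulate --out-dir demo --seed 5 --n-samples 8 --n-snps 4000 --mean-depth 50
mbmixups run --genotypes demo/genotypes.csv --counts-dir demo/counts --out study
```

(The planted anomalies above are written via the Python API's `scenarios`
config; see `mbmixups.SimulationConfig`.) The run prints:

```
mbmixups v0.1.0 study report
microbiome samples: 8, genotyped samples: 8, SNPs: 4000

verdict counts:
  correct          5
  swap             2
  mixture          1

anomalies:
  S002: swap, closest genomic sample S005 (d=0.0052, self d=0.2877)
  S005: swap, closest genomic sample S002 (d=0.0050, self d=0.2908)
  S007: mixture with S003 (p=0.303, eps=0.0052, LRT=2.16e+04)
```

Reading it: S002's reads are discordant with its own genotype at 28.8% of
homozygous sites (far beyond sequencing error) but agree with S005's
genotype to within 0.52% — the two labels are swapped. S007 is closest to
its own genotype but at distance 0.088, too far for a clean sample; the
mixture scan attributes it to S003 with p̂ = 0.303 (truth: 0.30) and
ε̂ = 0.0052 (truth: 0.005), with an LRT of 2.2×10⁴ that dwarfs every other
candidate's. Outputs land in `study/`: `verdicts.csv`, `distances.csv`,
per-sample scan tables, and diagnostic figures (min-distance vs
self-distance; LRT vs p̂).

The same pipeline is available as a library: `distance_matrix` /
`classify_samples` / `scan_contaminants` / `detect_contaminant` /
`run_study`, operating on a `GenotypeMatrix` (CSV or VCF; or imputed from
founder-diplotype probabilities via `impute_snp_genotypes`) and per-sample
allele-count TSVs (or extracted from an indexed BAM with
`extract_allele_counts`).

## Documentation

See `docs/methods.md` for the model, its assumptions, the synthetic-cohort
generator, numerical choices, and known limitations.
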