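"""Synthetic cohorts of host genotypes and microbiome allele counts.

Generates the two inputs the identity checks consume — a host SNP genotype
matrix and per-sample major/minor read counts at those SNPs — under the same
read model the mixture analysis fits: a read at a SNP carries the minor
allele with probability eps + f* (1 - 2 eps), where f* is the minor-allele
frequency of the (possibly mixed) template DNA.  Planted anomalies (label
swaps, two-sample mixtures) make every downstream module testable end to end
without external data.

Genotypes are drawn under Hardy-Weinberg equilibrium at per-SNP minor-allele
frequencies: the identity and mixture statistics depend only on genotype
frequencies and read counts, not on the pedigree that produced them, so the
multiparental founder-mosaic structure is not emulated here.  Read depth per
SNP is Poisson, with a per-sample log-uniform depth multiplier emulating the
wide variation in host-read fraction seen in real fecal shotgun data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import SnpAlleleCounts
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """True provenance of one microbiome sample.

    kind "correct": reads come from the labeled individual.
    kind "swap": reads come entirely from individual ``other``.
    kind "mixture": a proportion ``p`` of the host DNA comes from ``other``.
    """

    kind: str = "correct"
    other: str | None = None
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("correct", "swap", "mixture"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind != "correct" and self.other is None:
            raise ValueError(f"scenario {self.kind!r} needs an 'other' sample id")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"mixture proportion {self.p} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults describe a small but realistic cohort: per-SNP minor-allele
    frequencies uniform on [0.05, 0.5]; mean read depth 50 per SNP over
    2000 SNPs (~100k host reads per sample at multiplier 1); per-sample
    depth multipliers log-uniform over [0.1, 10]; sequencing error rate
    0.005.  A seed is mandatory: identical config + seed reproduces the
    cohort exactly.
    """

    seed: int
    n_samples: int = 20
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 50.0
    depth_multiplier_range: tuple[float, float] = (0.1, 10.0)
    eps_true: float = 0.005
    scenarios: dict[str, Scenario] = field(default_factory=dict)

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_samples + 1)]

    def snp_ids(self) -> list[str]:
        return [f"snp{j:05d}" for j in range(1, self.n_snps + 1)]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, for downstream scoring."""

    scenarios: dict[str, Scenario]
    eps_true: float
    maf: np.ndarray
    sample_depths: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "eps_true": self.eps_true,
            "scenarios": {
                sid: dataclasses.asdict(sc) for sid, sc in self.scenarios.items()
            },
            "sample_depths": self.sample_depths,
        }


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the host genotype matrix; returns (genotypes, per-SNP MAF).

    MAF ~ Uniform(maf_range) per SNP; minor-allele dosage ~ Binomial(2, MAF)
    per sample (Hardy-Weinberg).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_snps) if hi > lo else np.full(cfg.n_snps, lo)
    dose = rng.binomial(2, maf, size=(cfg.n_samples, cfg.n_snps)).astype(float)
    calls = pd.DataFrame(dose, index=cfg.sample_ids(), columns=cfg.snp_ids())
    return GenotypeMatrix(calls), maf


def simulate_read_counts(
    geno: GenotypeMatrix,
    sample_id: str,
    scenario: Scenario,
    rng: np.random.Generator,
    mean_depth: float = 50.0,
    eps_true: float = 0.005,
) -> SnpAlleleCounts:
    """Draw major/minor read counts for one microbiome sample.

    Per SNP, the read total is Poisson(mean_depth) and the minor-read count
    is Binomial(total, eps + f* (1 - 2 eps)), with f* the template
    minor-allele frequency under the scenario: the labeled individual's
    dosage/2 for "correct", the other individual's for "swap", and their
    (1-p)/p blend for "mixture".
    """
    if sample_id not in geno.calls.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    f_self = geno.dosage(sample_id) / 2.0
    if scenario.kind == "correct":
        f_star = f_self
    else:
        if scenario.other not in geno.calls.index:
            raise KeyError(f"scenario source {scenario.other!r} not in genotype matrix")
        f_other = geno.dosage(scenario.other) / 2.0
        if scenario.kind == "swap":
            f_star = f_other
        else:
            f_star = (1.0 - scenario.p) * f_self + scenario.p * f_other
    if np.isnan(f_star).any():
        raise ValueError("simulation requires complete genotypes for the source samples")
    n = rng.poisson(mean_depth, size=len(f_star))
    prob_minor = eps_true + f_star * (1.0 - 2.0 * eps_true)
    n_minor = rng.binomial(n, prob_minor)
    frame = pd.DataFrame(
        {"n_major": n - n_minor, "n_minor": n_minor},
        index=pd.Index(geno.snp_ids, name="snp_id"),
    )
    return SnpAlleleCounts(sample_id=sample_id, counts=frame)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, dict[str, SnpAlleleCounts], SimulationTruth]:
    """Genotypes plus one set of allele counts per sample, with ground truth.

    Samples without an entry in ``cfg.scenarios`` are correct.  All draws
    derive from ``cfg.seed``; samples are processed in id order, so identical
    config + seed gives identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    geno, maf = simulate_genotypes(cfg, rng)
    lo, hi = cfg.depth_multiplier_range
    ids = cfg.sample_ids()
    if hi > lo:
        mult = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
    else:
        mult = np.full(len(ids), lo)
    scenarios = {sid: cfg.scenarios.get(sid, Scenario()) for sid in ids}
    for sid, sc in scenarios.items():
        if sc.kind != "correct" and sc.other not in ids:
            raise ValueError(f"scenario for {sid} references unknown sample {sc.other!r}")
    counts: dict[str, SnpAlleleCounts] = {}
    depths: dict[str, float] = {}
    for sid, m in zip(ids, mult):
        depth = float(cfg.mean_depth * m)
        depths[sid] = depth
        counts[sid] = simulate_read_counts(
            geno, sid, scenarios[sid], rng, mean_depth=depth, eps_true=cfg.eps_true
        )
    truth = SimulationTruth(scenarios, cfg.eps_true, maf, depths)
    return geno, counts, truth


def make_benchmark_cohort(
    cfg: SimulationConfig, out_dir: str | Path, overwrite: bool = False
) -> Path:
    """Write a simulated cohort in the on-disk layout the CLI consumes.

    Produces ``genotypes.csv``, ``counts/<sample>.tsv`` and ``truth.json``
    under ``out_dir``; refuses to overwrite an existing cohort unless
    ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    geno_path = out_dir / "genotypes.csv"
    truth_path = out_dir / "truth.json"
    counts_dir = out_dir / "counts"
    if not overwrite and (geno_path.exists() or truth_path.exists() or counts_dir.exists()):
        raise FileExistsError(
            f"{out_dir} already contains a cohort; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_dir.mkdir(exist_ok=True)
    geno, counts, truth = simulate_cohort(cfg)
    geno.to_csv(geno_path)
    for sid, sac in counts.items():
        sac.to_tsv(counts_dir / f"{sid}.tsv")
    payload = truth.to_json_dict()
    payload["config"] = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_snps": cfg.n_snps,
        "maf_range": list(cfg.maf_range),
        "mean_depth": cfg.mean_depth,
        "depth_multiplier_range": list(cfg.depth_multiplier_range),
        "eps_true": cfg.eps_true,
    }
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    log.info("wrote benchmark cohort to %s", out_dir)
    return out_dir
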