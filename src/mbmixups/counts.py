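"""Tabulation of microbiome reads overlapping host SNPs into category tables.

Shotgun-metagenome reads from a fecal sample include a fraction derived from
the host.  At each biallelic SNP the reads carrying the major (A) versus the
minor (B) allele are counted; those counts, cross-classified by the SNP
genotype of one host sample (3x2 table) or of a pair of host samples
(3x3x2 table), are the raw material for the distance and mixture analyses.

Canonical ingestion is a per-sample allele-count TSV; extraction from an
aligned-read (BAM) file is provided as an optional utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GENOTYPE_LABELS, GenotypeMatrix

log = logging.getLogger(__name__)

ALLELE_LABELS = ("A", "B")


# ---------------------------------------------------------------------------
# Per-sample allele counts
# ---------------------------------------------------------------------------

@dataclass
class SnpAlleleCounts:
    """Counts of major/minor-allele reads per SNP for one microbiome sample.

    ``counts`` is indexed by snp_id with integer columns ``n_major`` and
    ``n_minor``.  SNPs absent from the table are implicitly zero-count.
    """

    sample_id: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.counts
        for col in ("n_major", "n_minor"):
            if col not in frame.columns:
                raise ValueError(f"allele-count table lacks column {col!r}")
        frame = frame[["n_major", "n_minor"]].astype(np.int64)
        if (frame.to_numpy() < 0).any():
            raise ValueError("allele counts must be non-negative")
        self.counts = frame

    @property
    def total_reads(self) -> int:
        """Total reads overlapping any SNP in the table."""
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV (snp_id, n_major, n_minor); .gz suffix compresses."""
        self.counts.to_csv(path, sep="\t", index_label="snp_id")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "SnpAlleleCounts":
        """Read an allele-count TSV; sample id defaults to the file stem."""
        path = Path(path)
        if sample_id is None:
            sample_id = path.name
            for suffix in (".gz", ".tsv", ".txt"):
                if sample_id.endswith(suffix):
                    sample_id = sample_id[: -len(suffix)]
        frame = pd.read_csv(path, sep="\t", index_col="snp_id", dtype={"snp_id": str})
        return cls(sample_id=sample_id, counts=frame)


def read_counts_dir(directory: str | Path) -> dict[str, SnpAlleleCounts]:
    """Load every allele-count TSV (``*.tsv`` / ``*.tsv.gz``) in a directory."""
    directory = Path(directory)
    out: dict[str, SnpAlleleCounts] = {}
    for path in sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.tsv.gz")):
        sac = SnpAlleleCounts.from_tsv(path)
        out[sac.sample_id] = sac
    if not out:
        raise FileNotFoundError(f"no allele-count TSV files in {directory}")
    return out


# ---------------------------------------------------------------------------
# Category tables
# ---------------------------------------------------------------------------

@dataclass
class CategoryTable:
    """3x2 read counts: (host genotype AA/AB/BB) x (read allele A/B)."""

    microbiome_id: str
    genomic_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 2):
            raise ValueError(f"category table must be 3x2, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("category counts must be non-negative")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with explicit category labels, for auditability."""
        rows = [
            (g, a, int(self.counts[i, j]))
            for i, g in enumerate(GENOTYPE_LABELS)
            for j, a in enumerate(ALLELE_LABELS)
        ]
        return pd.DataFrame(rows, columns=["genotype", "allele", "count"])


@dataclass
class JointCategoryTable:
    """3x3x2 read counts: (genotype of self) x (genotype of other) x (allele)."""

    microbiome_id: str
    genomic_id_self: str
    genomic_id_other: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3, 2):
            raise ValueError(f"joint category table must be 3x3x2, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("category counts must be non-negative")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal_self(self) -> CategoryTable:
        """Collapse over the other sample's genotype axis."""
        return CategoryTable(
            microbiome_id=self.microbiome_id,
            genomic_id=self.genomic_id_self,
            counts=self.counts.sum(axis=1),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g1, g2, a, int(self.counts[i, j, k]))
            for i, g1 in enumerate(GENOTYPE_LABELS)
            for j, g2 in enumerate(GENOTYPE_LABELS)
            for k, a in enumerate(ALLELE_LABELS)
        ]
        return pd.DataFrame(rows, columns=["genotype_self", "genotype_other", "allele", "count"])


def _aligned_arrays(
    reads: SnpAlleleCounts, geno: GenotypeMatrix, sample_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align read counts with genotype dosages on the common SNP set.

    Returns (n_major, n_minor, dosages) where dosages has one row per
    requested genotyped sample, restricted to SNPs present in both tables.
    """
    common = reads.counts.index.intersection(geno.calls.columns)
    nA = reads.counts.loc[common, "n_major"].to_numpy()
    nB = reads.counts.loc[common, "n_minor"].to_numpy()
    dose = geno.calls.loc[sample_ids, common].to_numpy()
    return nA, nB, dose


def tabulate_single(
    reads: SnpAlleleCounts, geno: GenotypeMatrix, genomic_id: str
) -> CategoryTable:
    """Count reads in the six categories (host genotype x read allele).

    SNPs where ``genomic_id`` has a missing genotype are excluded.
    """
    if genomic_id not in geno.calls.index:
        raise KeyError(f"unknown genotyped sample {genomic_id!r}")
    nA, nB, dose = _aligned_arrays(reads, geno, [genomic_id])
    d = dose[0]
    ok = ~np.isnan(d)
    g = d[ok].astype(np.int64)
    out = np.zeros((3, 2), dtype=np.int64)
    out[:, 0] = np.bincount(g, weights=nA[ok], minlength=3)[:3]
    out[:, 1] = np.bincount(g, weights=nB[ok], minlength=3)[:3]
    return CategoryTable(reads.sample_id, genomic_id, out)


def tabulate_pair(
    reads: SnpAlleleCounts, geno: GenotypeMatrix, id_self: str, id_other: str
) -> JointCategoryTable:
    """Count reads split by the joint genotypes of a pair of host samples.

    SNPs where either genotype is missing are excluded entirely.
    """
    if id_self == id_other:
        raise ValueError(f"degenerate pair: id_self == id_other == {id_self!r}")
    for sid in (id_self, id_other):
        if sid not in geno.calls.index:
            raise KeyError(f"unknown genotyped sample {sid!r}")
    nA, nB, dose = _aligned_arrays(reads, geno, [id_self, id_other])
    d1, d2 = dose
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    cell = (d1[ok] * 3 + d2[ok]).astype(np.int64)
    out = np.zeros((3, 3, 2), dtype=np.int64)
    out[:, :, 0] = np.bincount(cell, weights=nA[ok], minlength=9)[:9].reshape(3, 3)
    out[:, :, 1] = np.bincount(cell, weights=nB[ok], minlength=9)[:9].reshape(3, 3)
    return JointCategoryTable(reads.sample_id, id_self, id_other, out)


# ---------------------------------------------------------------------------
# Pileup extraction from aligned reads (optional utility)
# ---------------------------------------------------------------------------

def extract_allele_counts(
    alignment: str | Path,
    sites: pd.DataFrame,
    sample_id: str | None = None,
    min_base_quality: int = 20,
    min_mapping_quality: int = 0,
) -> SnpAlleleCounts:
    """Count major/minor-allele reads at SNP sites from a coordinate-sorted,
    indexed alignment file.

    ``sites`` needs columns snp_id, chrom, pos (1-based), major, minor.
    Each aligned read segment is counted once per overlapped site; paired-end
    mates are counted independently.  Bases matching neither allele are
    discarded and tallied in a log summary.  Bases below ``min_base_quality``
    (default 20) and reads below ``min_mapping_quality`` are skipped.
    """
    import pysam

    alignment = Path(alignment)
    required = {"snp_id", "chrom", "pos", "major", "minor"}
    if not required <= set(sites.columns):
        raise ValueError(f"sites table needs columns {sorted(required)}")

    with pysam.AlignmentFile(str(alignment)) as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{alignment} has no index; sort and index it (e.g. samtools index)"
            )
        refs = set(bam.references)
        unmatched = sorted(set(sites["chrom"].astype(str)) - refs)
        if unmatched:
            raise ValueError(
                f"contigs in site list not present in {alignment.name}: {unmatched}"
            )
        n_other = 0
        records = []
        for row in sites.itertuples(index=False):
            pos0 = int(row.pos) - 1
            n_major = n_minor = 0
            for col in bam.pileup(
                str(row.chrom),
                pos0,
                pos0 + 1,
                truncate=True,
                min_base_quality=min_base_quality,
                min_mapping_quality=min_mapping_quality,
            ):
                if col.reference_pos != pos0:
                    continue
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    base = pr.alignment.query_sequence[pr.query_position].upper()
                    if base == row.major:
                        n_major += 1
                    elif base == row.minor:
                        n_minor += 1
                    else:
                        n_other += 1
            records.append((row.snp_id, n_major, n_minor))
    if n_other:
        log.info(
            "extract_allele_counts: discarded %d read base(s) matching neither allele",
            n_other,
        )
    frame = pd.DataFrame(records, columns=["snp_id", "n_major", "n_minor"]).set_index(
        "snp_id"
    )
    if sample_id is None:
        sample_id = alignment.stem
    return SnpAlleleCounts(sample_id=sample_id, counts=frame)
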