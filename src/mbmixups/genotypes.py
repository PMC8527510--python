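"""Preparation of the dense host SNP genotype matrix.

Host individuals from a multiparental cross (e.g. an eight-founder advanced
intercross) carry mosaics of founder haplotypes.  Given (a) a table of founder
alleles at a dense set of SNPs and (b) per-individual diplotype (founder-pair)
probabilities at those SNPs, this module collapses the diplotype probabilities
to 3-state SNP genotype calls {AA, AB, BB}, where A denotes the major allele
among the founders and B the minor allele.

Genotypes are held internally as minor-allele dosage: 0 (AA), 1 (AB), 2 (BB),
with NaN for missing.  File I/O accepts both letter and dosage encodings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical order of the three genotype states (index = minor-allele dosage).
GENOTYPE_LABELS = ("AA", "AB", "BB")

#: Reserved (non-founder) columns of a founder SNP table.
FOUNDER_META_COLS = ("snp_id", "chrom", "pos")

_VALID_BASES = frozenset("ACGT")
_MISSING_TOKENS = frozenset({"", "N", "-", ".", "NA", "nan"})


# ---------------------------------------------------------------------------
# Founder SNP table
# ---------------------------------------------------------------------------

def founder_allele_columns(table: pd.DataFrame) -> list[str]:
    """Names of the founder-strain allele columns of a founder SNP table."""
    return [c for c in table.columns if c not in FOUNDER_META_COLS]


def read_founder_table(path: str | Path) -> pd.DataFrame:
    """Read a founder SNP table (TSV: snp_id, chrom, pos, one column per founder).

    Positions are 1-based.  Founder alleles are single nucleotides; any of
    "", "N", "-", "." is treated as missing.
    """
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in FOUNDER_META_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"founder table {path} lacks required columns {missing}")
    if not founder_allele_columns(table):
        raise ValueError(f"founder table {path} has no founder allele columns")
    return table


def _allele_matrix(table: pd.DataFrame) -> np.ndarray:
    """Founder alleles as an (n_snps, k) array of upper-case strings, '' = missing."""
    cols = founder_allele_columns(table)
    mat = table[cols].astype(str).to_numpy().astype("U8")
    mat = np.char.upper(np.char.strip(mat))
    for tok in _MISSING_TOKENS:
        mat[mat == tok.upper()] = ""
    return mat


def filter_biallelic(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only SNPs with exactly two distinct founder alleles.

    SNPs with more than two alleles among the founders are uninformative for
    a biallelic major/minor coding and are omitted.  Monomorphic SNPs carry no
    identity information and are dropped likewise, as are SNPs with any
    missing founder allele (the diplotype-to-genotype map is undefined there).
    Row order is preserved.
    """
    if table.empty:
        raise ValueError("empty founder table")
    mat = _allele_matrix(table)
    keep = np.zeros(len(table), dtype=bool)
    for i, row in enumerate(mat):
        alleles = set(row)
        if "" in alleles:
            continue
        if not alleles <= _VALID_BASES:
            continue
        keep[i] = len(alleles) == 2
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_biallelic: dropped %d of %d SNPs", n_drop, len(table))
    return table.loc[keep].reset_index(drop=True)


def code_alleles(table: pd.DataFrame) -> pd.DataFrame:
    """Assign major/minor allele codes per SNP from founder-strain frequency.

    The major allele is the one carried by more founders; on a tie, the
    lexicographically smaller nucleotide is major, making the coding
    deterministic and independent of founder ordering.

    Returns a DataFrame with columns ``snp_id``, ``major``, ``minor``.
    Raises ``ValueError`` on any SNP without exactly two alleles (run
    :func:`filter_biallelic` first).
    """
    mat = _allele_matrix(table)
    majors = np.empty(len(table), dtype=object)
    minors = np.empty(len(table), dtype=object)
    for i, row in enumerate(mat):
        alleles, counts = np.unique(row, return_counts=True)
        if len(alleles) != 2 or "" in alleles:
            raise ValueError(
                f"SNP {table['snp_id'].iloc[i]} is not biallelic "
                f"(alleles {sorted(set(row))}); apply filter_biallelic first"
            )
        a, b = alleles  # np.unique sorts, so a < b lexicographically
        ca, cb = counts
        if ca > cb or (ca == cb):  # tie -> lexicographically smaller (a)
            majors[i], minors[i] = a, b
        else:
            majors[i], minors[i] = b, a
    return pd.DataFrame(
        {"snp_id": table["snp_id"].to_numpy(), "major": majors, "minor": minors}
    )


# ---------------------------------------------------------------------------
# Diplotype probabilities
# ---------------------------------------------------------------------------

def diplotype_states(n_founders: int) -> list[tuple[int, int]]:
    """Unordered founder-pair states, in lexicographic order.

    For k founders there are k(k+1)/2 states (36 for k = 8), ordered
    (0,0), (0,1), ..., (0,k-1), (1,1), (1,2), ...
    """
    return list(itertools.combinations_with_replacement(range(n_founders), 2))


@dataclass
class DiplotypeProbs:
    """Per-sample, per-SNP probabilities over the unordered founder-pair states.

    ``probs`` has shape (n_samples, n_snps, d) with d = k(k+1)/2 and rows
    summing to 1; the state order is that of :func:`diplotype_states`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    probs: np.ndarray
    n_founders: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        d = len(diplotype_states(self.n_founders))
        expect = (len(self.sample_ids), len(self.snp_ids), d)
        if self.probs.shape != expect:
            raise ValueError(
                f"diplotype probs shape {self.probs.shape} != expected {expect}"
            )

    def validate(self, atol: float = 1e-6) -> None:
        """Check that each probability vector sums to 1 within ``atol``."""
        sums = self.probs.sum(axis=2)
        bad = ~np.isclose(sums, 1.0, atol=atol, rtol=0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"diplotype probabilities for sample {self.sample_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r} sum to {sums[i, j]:.8f}, not 1"
            )


def average_flanking_probs(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Diplotype probabilities for SNPs between two array markers.

    Assumes diplotype probabilities are constant within the interval between
    typed markers and uses the arithmetic mean of the two endpoint
    probability vectors.  An optional pre-step before imputation.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("flanking probability arrays must have equal shape")
    return 0.5 * (left + right)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

_LETTER_TO_DOSE = {"AA": 0.0, "AB": 1.0, "BA": 1.0, "BB": 2.0}
_DOSE_TO_LETTER = {0.0: "AA", 1.0: "AB", 2.0: "BB"}


@dataclass
class GenotypeMatrix:
    """Host SNP calls per sample, as minor-allele dosage.

    ``calls`` is a samples x SNPs DataFrame with float values in {0, 1, 2}
    (minor-allele dosage: AA=0, AB=1, BB=2) and NaN for missing.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        calls = self.calls.astype(float)
        values = calls.to_numpy()
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok][0]
            raise ValueError(f"genotype dosage must be 0, 1, 2 or missing; got {bad!r}")
        calls.index.name = None
        calls.columns.name = None
        self.calls = calls

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def dosage(self, sample_id: str) -> np.ndarray:
        """Minor-allele dosage vector for one sample (NaN = missing)."""
        if sample_id not in self.calls.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.calls.loc[sample_id].to_numpy()

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path, letters: bool = True) -> None:
        """Write as CSV: header = snp ids, one row per sample.

        ``letters=True`` writes AA/AB/BB/NA; otherwise dosage 0/1/2/NA.
        """
        if letters:
            frame = self.calls.map(lambda v: _DOSE_TO_LETTER.get(v, "NA"))
        else:
            frame = self.calls.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        frame.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a genotype CSV written by :meth:`to_csv` (letters or dosage)."""
        raw = pd.read_csv(path, index_col=0, dtype=str)

        def decode(v: object) -> float:
            s = str(v).strip().upper()
            if s in _MISSING_TOKENS:
                return np.nan
            if s in _LETTER_TO_DOSE:
                return _LETTER_TO_DOSE[s]
            try:
                return float(s)
            except ValueError:
                raise ValueError(f"unrecognized genotype call {v!r}") from None

        return cls(raw.map(decode))

    @classmethod
    def from_vcf(cls, path: str | Path, coding: pd.DataFrame) -> "GenotypeMatrix":
        """Read diploid GT calls from a VCF, oriented to an allele coding.

        Variants are matched to ``coding`` rows (columns snp_id/major/minor)
        by the VCF ID field when set, else by "chrom:pos".  A variant whose
        {REF, ALT} does not equal {major, minor} is dropped with a warning.
        GT values 0/0, 0/1, 1/1 map to minor-allele dosage after orienting
        REF/ALT against major/minor; ./. maps to missing.
        """
        import pysam

        coding_by_id = coding.set_index("snp_id")
        rows: dict[str, dict[str, float]] = {}
        n_dropped = 0
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                key = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
                if key not in coding_by_id.index:
                    continue
                major = coding_by_id.at[key, "major"]
                minor = coding_by_id.at[key, "minor"]
                alts = rec.alts or ()
                if len(alts) != 1 or {rec.ref, alts[0]} != {major, minor}:
                    log.warning(
                        "VCF variant %s (%s/%s) does not match coding %s/%s; dropped",
                        key, rec.ref, alts[0] if alts else ".", major, minor,
                    )
                    n_dropped += 1
                    continue
                minor_is_alt = alts[0] == minor
                col: dict[str, float] = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        col[s] = np.nan
                    else:
                        n_alt = float(sum(gt))
                        col[s] = n_alt if minor_is_alt else len(gt) - n_alt
                rows[key] = col
        if n_dropped:
            log.warning("from_vcf: dropped %d variant(s) not matching the coding", n_dropped)
        frame = pd.DataFrame(rows)
        return cls(frame)


# ---------------------------------------------------------------------------
# Diplotype -> SNP genotype collapse
# ---------------------------------------------------------------------------

def _state_dosage_map(
    table: pd.DataFrame, coding: pd.DataFrame, snp_ids: Sequence[str], n_founders: int
) -> np.ndarray:
    """Minor-allele dosage implied by each diplotype state at each SNP.

    Returns an (n_snps, d) integer array: dosage of state (i, j) is the number
    of its two founder haplotypes carrying the minor allele.  Assumes inbred
    founders (one haploid allele per founder per SNP).
    """
    table_by_id = table.set_index("snp_id")
    coding_by_id = coding.set_index("snp_id")
    founder_cols = founder_allele_columns(table)
    if len(founder_cols) != n_founders:
        raise ValueError(
            f"founder table has {len(founder_cols)} founders, expected {n_founders}"
        )
    states = diplotype_states(n_founders)
    out = np.empty((len(snp_ids), len(states)), dtype=np.int64)
    for s, snp in enumerate(snp_ids):
        if snp not in table_by_id.index:
            raise KeyError(f"SNP {snp!r} not in founder table")
        if snp not in coding_by_id.index:
            raise KeyError(f"SNP {snp!r} not in allele coding")
        minor = coding_by_id.at[snp, "minor"]
        alleles = table_by_id.loc[snp, founder_cols].astype(str).str.upper()
        carries_minor = (alleles == minor).to_numpy().astype(np.int64)
        for t, (i, j) in enumerate(states):
            out[s, t] = carries_minor[i] + carries_minor[j]
    return out


def genotype_marginals(
    dip: DiplotypeProbs, table: pd.DataFrame, coding: pd.DataFrame
) -> np.ndarray:
    """Marginal P(AA), P(AB), P(BB) per sample per SNP.

    Sums diplotype-state probabilities whose founder-allele pair implies each
    3-state genotype.  Shape (n_samples, n_snps, 3); slices along the last
    axis sum to 1 wherever the input probabilities do.
    """
    dip.validate()
    dose = _state_dosage_map(table, coding, dip.snp_ids, dip.n_founders)
    marg = np.empty((len(dip.sample_ids), len(dip.snp_ids), 3))
    for g in range(3):
        marg[:, :, g] = np.einsum("ijt,jt->ij", dip.probs, (dose == g).astype(float))
    return marg


def impute_snp_genotypes(
    dip: DiplotypeProbs,
    table: pd.DataFrame,
    coding: pd.DataFrame,
    threshold: float = 0.95,
) -> GenotypeMatrix:
    """Collapse diplotype probabilities to 3-state SNP calls.

    The call at a SNP is the genotype with maximum marginal probability,
    provided that probability exceeds ``threshold`` (default 0.95); otherwise
    the call is missing.
    """
    marg = genotype_marginals(dip, table, coding)
    best = marg.argmax(axis=2).astype(float)
    best[marg.max(axis=2) <= threshold] = np.nan
    calls = pd.DataFrame(best, index=list(dip.sample_ids), columns=list(dip.snp_ids))
    return GenotypeMatrix(calls)
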