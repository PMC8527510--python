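"""Genotype-discordance distance between microbiome and genomic DNA samples.

The distance between a microbiome sample and a genotyped host sample is the
proportion of reads carrying a discordant allele, among reads that overlap a
SNP where the genotyped sample is homozygous: at AA SNPs the reads should be
(nearly) all A, at BB SNPs all B, so under a correct label the distance
approximates the sequencing error rate, while against an unrelated individual
it is large.  Heterozygous SNPs are uninformative here and are ignored.

A matrix of all microbiome x genomic distances supports detection of sample
mix-ups (a sample much closer to another individual's DNA than to its own)
and flags candidates for the mixture analysis.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CategoryTable, SnpAlleleCounts
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

LABELS = (
    "correct",
    "swap",
    "mixture_candidate",
    "low_quality_dna",
    "low_reads",
    "unresolved",
)


def discordance_distance(t: CategoryTable) -> float:
    """Proportion of discordant reads at homozygous-genotype SNPs.

    d = [n(AA,B) + n(BB,A)] / [n(AA,A) + n(AA,B) + n(BB,A) + n(BB,B)].
    The heterozygous row is ignored.  Returns NaN (flagged, never silently 0)
    when no reads fall in the homozygous rows.
    """
    c = t.counts
    denom = int(c[0].sum() + c[2].sum())
    if denom == 0:
        log.warning(
            "distance %s vs %s undefined: no reads at homozygous SNPs",
            t.microbiome_id,
            t.genomic_id,
        )
        return float("nan")
    return float((c[0, 1] + c[2, 0]) / denom)


@dataclass
class DistanceResult:
    """All pairwise discordance distances plus the read totals behind them.

    ``distances``: microbiome rows x genomic columns, NaN where undefined.
    ``informative_reads``: homozygous-SNP read totals per pair (the
    denominators of the distances).
    ``total_reads``: per microbiome sample, total reads overlapping any SNP.
    """

    distances: pd.DataFrame
    informative_reads: pd.DataFrame
    total_reads: pd.Series


def distance_matrix(
    counts: Mapping[str, SnpAlleleCounts] | Iterable[SnpAlleleCounts],
    geno: GenotypeMatrix,
) -> DistanceResult:
    """Discordance distance from every microbiome sample to every genotyped sample.

    Equivalent to ``discordance_distance(tabulate_single(reads_i, geno, j))``
    for every pair (i, j), computed by matrix products over the genotype
    dosage masks.
    """
    if isinstance(counts, Mapping):
        counts_list = list(counts.values())
    else:
        counts_list = list(counts)
    if not counts_list or not len(geno.calls):
        raise ValueError("empty microbiome or genotype collection")

    genomic_ids = geno.sample_ids
    G = geno.calls.to_numpy()  # (n_geno, n_snps)
    dist = np.full((len(counts_list), len(genomic_ids)), np.nan)
    denom_out = np.zeros_like(dist)
    totals = []
    mb_ids = []
    snp_index = geno.calls.columns
    for i, sac in enumerate(counts_list):
        mb_ids.append(sac.sample_id)
        totals.append(sac.total_reads)
        idx = snp_index.get_indexer(sac.counts.index)
        present = idx >= 0
        nA = sac.counts["n_major"].to_numpy(dtype=float)[present]
        nB = sac.counts["n_minor"].to_numpy(dtype=float)[present]
        Gsub = G[:, idx[present]]
        is_aa = (Gsub == 0.0).astype(float)
        is_bb = (Gsub == 2.0).astype(float)
        discordant = is_aa @ nB + is_bb @ nA
        denom = is_aa @ (nA + nB) + is_bb @ (nA + nB)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, discordant / np.maximum(denom, 1.0), np.nan)
        dist[i] = d
        denom_out[i] = denom
        if (denom == 0).any():
            log.warning(
                "sample %s: distance undefined against %d genotyped sample(s)",
                sac.sample_id,
                int((denom == 0).sum()),
            )
    return DistanceResult(
        distances=pd.DataFrame(dist, index=mb_ids, columns=genomic_ids),
        informative_reads=pd.DataFrame(denom_out, index=mb_ids, columns=genomic_ids),
        total_reads=pd.Series(totals, index=mb_ids, name="total_reads"),
    )


@dataclass
class ClassificationThresholds:
    """Decision thresholds for :func:`classify_samples`.

    self_high: self-distance above which a sample cannot be its own label.
    match_low: distance below which a genotyped sample is a clear match.
    mixture_gray: self-distance above which a self-closest sample is
        nevertheless suspicious (candidate mixture).
    low_reads_floor: minimum total reads overlapping SNPs for a sample to be
        classifiable at all.
    """

    self_high: float = 0.15
    match_low: float = 0.01
    mixture_gray: float = 0.05
    low_reads_floor: int = 100_000


def classify_samples(
    result: DistanceResult,
    thresholds: ClassificationThresholds | None = None,
    low_quality_dna_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Classify each microbiome sample from its row of the distance matrix.

    Labels, in decision order:

    - ``unresolved`` if there is no same-named genomic column or the row is
      entirely undefined;
    - ``correct`` if the self-distance is < match_low and self is the closest;
    - ``swap`` if the self-distance is > self_high while some other sample is
      closer than match_low;
    - ``low_quality_dna`` if the sample's genomic DNA is in the caller-supplied
      low-quality set (DNA quality is not derivable from the distances);
    - ``mixture_candidate`` if the minimum distance sits in
      [match_low, self_high), or self is closest but at a distance in
      [mixture_gray, self_high) — close to two samples, or not close to any;
    - ``low_reads`` if total reads overlapping SNPs fall below the floor;
    - ``unresolved`` otherwise.

    Ties for the closest sample are broken by column order with a warning.
    Undefined (NaN) distances are excluded from the minimum.
    """
    th = thresholds or ClassificationThresholds()
    lq = set(low_quality_dna_ids)
    dm = result.distances
    rows = []
    for mb_id, row in dm.iterrows():
        values = row.to_numpy()
        defined = ~np.isnan(values)
        self_distance = float(row[mb_id]) if mb_id in dm.columns else np.nan
        total = int(result.total_reads[mb_id])
        if not defined.any():
            rows.append((mb_id, self_distance, np.nan, None, None, total, "unresolved"))
            continue
        order = np.argsort(values[defined], kind="stable")
        defined_cols = dm.columns[defined]
        argmin_id = defined_cols[order[0]]
        min_distance = float(values[defined][order[0]])
        second_id = defined_cols[order[1]] if len(order) > 1 else None
        if len(order) > 1 and values[defined][order[1]] == min_distance:
            log.warning(
                "sample %s: tie for closest genomic sample (%s, %s); kept column order",
                mb_id, argmin_id, second_id,
            )
        if mb_id not in dm.columns or np.isnan(self_distance):
            label = "unresolved"
        elif self_distance < th.match_low and argmin_id == mb_id:
            label = "correct"
        elif (
            self_distance > th.self_high
            and min_distance < th.match_low
            and argmin_id != mb_id
        ):
            label = "swap"
        elif mb_id in lq:
            label = "low_quality_dna"
        elif th.match_low <= min_distance < th.self_high or (
            argmin_id == mb_id and th.mixture_gray <= self_distance < th.self_high
        ):
            label = "mixture_candidate"
        elif total < th.low_reads_floor:
            label = "low_reads"
        else:
            label = "unresolved"
        rows.append(
            (mb_id, self_distance, min_distance, argmin_id, second_id, total, label)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "microbiome_id",
            "self_distance",
            "min_distance",
            "argmin_id",
            "second_argmin_id",
            "total_reads",
            "label",
        ],
    )


def match_table(result: DistanceResult, microbiome_id: str) -> pd.DataFrame:
    """Genomic samples ranked by ascending distance to one microbiome sample.

    Ties keep column order (stable sort).  Undefined distances are placed
    last with rank NaN.  Rank 1 is the closest match; "second-closest"
    queries read off rank 2.
    """
    if microbiome_id not in result.distances.index:
        raise KeyError(f"unknown microbiome sample {microbiome_id!r}")
    row = result.distances.loc[microbiome_id]
    frame = pd.DataFrame(
        {"genomic_id": row.index, "distance": row.to_numpy()}
    )
    frame = frame.sort_values(
        "distance", kind="stable", na_position="last"
    ).reset_index(drop=True)
    ranks = np.where(
        np.isnan(frame["distance"].to_numpy()),
        np.nan,
        np.arange(1, len(frame) + 1, dtype=float),
    )
    frame["rank"] = ranks
    return frame


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

_LABEL_COLORS = {
    "correct": "#3b7dd8",
    "swap": "#4b0082",
    "mixture_candidate": "#2e8b57",
    "low_quality_dna": "#fa8072",
    "low_reads": "#b39ddb",
    "unresolved": "#999999",
}


def plot_min_vs_self(calls: pd.DataFrame, ax=None):
    """Scatter of minimum distance vs distance to self, colored by label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for label, grp in calls.groupby("label"):
        ax.scatter(
            grp["self_distance"],
            grp["min_distance"],
            s=18,
            label=f"{label} (n={len(grp)})",
            color=_LABEL_COLORS.get(label, "#333333"),
            alpha=0.8,
        )
    lim = max(
        np.nanmax(calls["self_distance"].to_numpy(dtype=float), initial=0.0),
        np.nanmax(calls["min_distance"].to_numpy(dtype=float), initial=0.0),
    )
    ax.plot([0, lim], [0, lim], ls=":", lw=0.8, color="gray")
    ax.set_xlabel("distance to self")
    ax.set_ylabel("minimum distance")
    ax.legend(fontsize=8)
    return ax


def plot_sample_distances(result: DistanceResult, microbiome_id: str, ax=None):
    """Distances from one microbiome sample to every genomic sample, in
    column order, with the same-named sample highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    row = result.distances.loc[microbiome_id]
    x = np.arange(len(row))
    ax.scatter(x, row.to_numpy(), s=10, color="#888888")
    if microbiome_id in row.index:
        i = row.index.get_loc(microbiome_id)
        ax.scatter([i], [row.iloc[i]], s=40, color="#d81b60", zorder=3, label="self")
        ax.legend(fontsize=8)
    ax.set_xlabel("genomic DNA sample")
    ax.set_ylabel("distance")
    ax.set_title(microbiome_id)
    return ax
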