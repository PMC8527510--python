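"""End-to-end study orchestration: distance -> classify -> scan -> verdicts.

Runs the full sample-identity check over a cohort: the discordance-distance
matrix and per-sample classification first, then the contaminant scan (by
default over every sample, since mixtures with small contaminant proportions
can look perfectly fine in the distance analysis), and finally one verdict
per microbiome sample.  Verdict precedence is swap > mixture > low_reads:
a clear label swap is reported as such even though the mixture scan will
also fire on it (with p near 1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .counts import SnpAlleleCounts
from .distance import (
    ClassificationThresholds,
    DistanceResult,
    classify_samples,
    distance_matrix,
    plot_min_vs_self,
)
from .genotypes import GenotypeMatrix
from .mixture import (
    ContaminantScan,
    boundary_lrt_critical,
    detect_contaminant,
    plot_cohort_lrt,
    plot_scan,
    scan_contaminants,
)

log = logging.getLogger(__name__)

VERDICTS = ("correct", "swap", "mixture", "low_reads", "low_quality_dna", "unresolved")

VERDICT_COLUMNS = [
    "microbiome_id",
    "verdict",
    "source_id",
    "contaminant_id",
    "p_hat",
    "eps_hat",
    "lrt",
    "separation",
    "self_distance",
    "min_distance",
    "argmin_id",
    "total_reads",
]


@dataclass
class StudyConfig:
    """All tunable thresholds of the full analysis."""

    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    gap_factor: float = 10.0
    #: family-wise level for the minimum-evidence floor of the separation
    #: rule, Bonferroni-adjusted over every fit in the cohort scan.
    alpha: float = 0.05
    #: scan every sample (None = auto: on for cohorts of <= 500 genotyped
    #: samples, since subtle mixtures can look correct in the distance step).
    scan_all: bool | None = None
    low_quality_dna_ids: tuple[str, ...] = ()
    call_threshold: float = 0.95  # genotype-imputation threshold, recorded for provenance

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        th_keys = {f.name for f in dataclasses.fields(ClassificationThresholds)}
        th = ClassificationThresholds(**{k: v for k, v in raw.items() if k in th_keys})
        kwargs = {}
        for key in ("gap_factor", "scan_all", "call_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        if "low_quality_dna_ids" in raw:
            kwargs["low_quality_dna_ids"] = tuple(raw["low_quality_dna_ids"])
        return cls(thresholds=th, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class StudyReport:
    """Final per-sample verdicts plus the evidence behind them."""

    verdicts: pd.DataFrame
    calls: pd.DataFrame
    distance_result: DistanceResult
    scans: dict[str, ContaminantScan]
    metadata: dict


def _digest_inputs(geno: GenotypeMatrix, counts: Mapping[str, SnpAlleleCounts]) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(geno.calls, index=True).to_numpy().tobytes())
    for sid in sorted(counts):
        h.update(sid.encode())
        h.update(pd.util.hash_pandas_object(counts[sid].counts, index=True).to_numpy().tobytes())
    return h.hexdigest()


def run_study(
    geno: GenotypeMatrix,
    counts: Mapping[str, SnpAlleleCounts],
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the complete mix-up / mixture analysis for a cohort.

    Deterministic given inputs and config.  Per-sample scan failures are
    recorded in the report metadata and do not abort the run.
    """
    cfg = config or StudyConfig()
    overlap = set(counts) & set(geno.sample_ids)
    if not overlap:
        raise ValueError("no sample-id overlap between allele counts and genotypes")

    t0 = time.perf_counter()
    result = distance_matrix(counts, geno)
    calls = classify_samples(result, cfg.thresholds, cfg.low_quality_dna_ids)
    t1 = time.perf_counter()
    log.info("distance + classification: %.2fs", t1 - t0)

    scan_all = cfg.scan_all
    if scan_all is None:
        scan_all = len(geno.sample_ids) <= 500
    if scan_all:
        to_scan = [sid for sid in counts if sid in geno.calls.index]
    else:
        flagged = calls.loc[calls["label"] != "correct", "microbiome_id"]
        to_scan = [sid for sid in flagged if sid in geno.calls.index]

    n_candidates = max(len(geno.sample_ids) - 1, 1)
    min_lrt = boundary_lrt_critical(max(len(to_scan), 1) * n_candidates, cfg.alpha)
    scans: dict[str, ContaminantScan] = {}
    failures: dict[str, str] = {}
    for sid in to_scan:
        try:
            scan = scan_contaminants(counts[sid], geno, sid)
            detect_contaminant(scan, cfg.gap_factor, min_lrt=min_lrt)
            scans[sid] = scan
        except Exception as exc:  # record and continue; partial cohorts are useful
            log.warning("contaminant scan failed for %s: %s", sid, exc)
            failures[sid] = str(exc)
    t2 = time.perf_counter()
    log.info("contaminant scans (%d samples): %.2fs", len(to_scan), t2 - t1)

    rows = []
    for call in calls.itertuples(index=False):
        sid = call.microbiome_id
        scan = scans.get(sid)
        top = scan.fits[scan.flagged_contaminant] if scan and scan.flagged_contaminant else None
        if call.label == "swap":
            verdict, source, contaminant = "swap", call.argmin_id, None
            p_hat = eps_hat = lrt = np.nan
        elif top is not None:
            verdict, source, contaminant = "mixture", None, scan.flagged_contaminant
            p_hat, eps_hat, lrt = top.p_hat, top.eps_hat, top.lrt
        elif call.label in ("low_reads", "low_quality_dna", "correct"):
            verdict, source, contaminant = call.label, None, None
            p_hat = eps_hat = lrt = np.nan
        else:
            verdict, source, contaminant = "unresolved", None, None
            p_hat = eps_hat = lrt = np.nan
        rows.append(
            {
                "microbiome_id": sid,
                "verdict": verdict,
                "source_id": source,
                "contaminant_id": contaminant,
                "p_hat": p_hat,
                "eps_hat": eps_hat,
                "lrt": lrt,
                "separation": scan.separation if scan else np.nan,
                "self_distance": call.self_distance,
                "min_distance": call.min_distance,
                "argmin_id": call.argmin_id,
                "total_reads": call.total_reads,
            }
        )
    verdicts = pd.DataFrame(rows, columns=VERDICT_COLUMNS)

    metadata = {
        "version": __version__,
        "config": cfg.to_dict(),
        "n_microbiome_samples": len(counts),
        "n_genotyped_samples": len(geno.sample_ids),
        "n_snps": len(geno.snp_ids),
        "input_digest": _digest_inputs(geno, counts),
        "scan_all": bool(scan_all),
        "scan_failures": failures,
        "per_sample_total_reads": {k: int(v) for k, v in result.total_reads.items()},
        "timings_s": {"distance": round(t1 - t0, 3), "scans": round(t2 - t1, 3)},
    }
    return StudyReport(verdicts, calls, result, scans, metadata)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_report(report: StudyReport, out_dir: str | Path, figures: bool = True) -> Path:
    """Write verdicts, per-sample scan tables, metadata, figures and a summary.

    Layout: verdicts.csv, distances.csv, scans/<sample>_scan.csv,
    metadata.json, summary.txt, figures/*.png.  Column order is stable.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        report.verdicts.to_csv(out_dir / "verdicts.csv", index=False)
        report.distance_result.distances.to_csv(out_dir / "distances.csv", index_label="microbiome_id")
        scans_dir = out_dir / "scans"
        scans_dir.mkdir(exist_ok=True)
        for sid, scan in report.scans.items():
            scan.results.to_csv(scans_dir / f"{sid}_scan.csv", index=False)
        (out_dir / "metadata.json").write_text(
            json.dumps(report.metadata, indent=2, sort_keys=True, default=str) + "\n"
        )
        (out_dir / "summary.txt").write_text(summarize(report))
        if figures:
            import matplotlib

            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            figs_dir = out_dir / "figures"
            figs_dir.mkdir(exist_ok=True)
            if len(report.calls):
                ax = plot_min_vs_self(report.calls)
                ax.figure.savefig(figs_dir / "min_vs_self.png", dpi=120)
                plt.close(ax.figure)
            cohort = _cohort_scan_summary(report)
            if len(cohort):
                ax = plot_cohort_lrt(cohort)
                ax.figure.savefig(figs_dir / "cohort_lrt.png", dpi=120)
                plt.close(ax.figure)
            for sid, scan in report.scans.items():
                if scan.flagged_contaminant is not None:
                    ax = plot_scan(scan)
                    ax.figure.savefig(figs_dir / f"scan_{sid}.png", dpi=120)
                    plt.close(ax.figure)
    except OSError as exc:
        raise OSError(f"failed writing report under {out_dir}: {exc}") from exc
    return out_dir


def _cohort_scan_summary(report: StudyReport) -> pd.DataFrame:
    rows = []
    verdict_by_id = dict(zip(report.verdicts["microbiome_id"], report.verdicts["verdict"]))
    for sid, scan in report.scans.items():
        if not len(scan.results):
            continue
        top = scan.results.iloc[0]
        rows.append(
            {
                "microbiome_id": sid,
                "p_hat": top["p_hat"],
                "lrt": top["lrt"],
                "verdict": verdict_by_id.get(sid, "unresolved"),
            }
        )
    return pd.DataFrame(rows, columns=["microbiome_id", "p_hat", "lrt", "verdict"])


def read_verdicts(path: str | Path) -> pd.DataFrame:
    """Read back a verdicts.csv written by :func:`write_report`."""
    frame = pd.read_csv(path, dtype={"microbiome_id": str})
    for col in ("source_id", "contaminant_id", "argmin_id"):
        frame[col] = frame[col].astype(object).where(frame[col].notna(), None)
    return frame[VERDICT_COLUMNS]


def summarize(report: StudyReport) -> str:
    """Human-readable cohort summary."""
    lines = [
        f"mbmixups v{report.metadata['version']} study report",
        f"microbiome samples: {report.metadata['n_microbiome_samples']}, "
        f"genotyped samples: {report.metadata['n_genotyped_samples']}, "
        f"SNPs: {report.metadata['n_snps']}",
        "",
        "verdict counts:",
    ]
    counts = report.verdicts["verdict"].value_counts()
    for verdict in VERDICTS:
        if verdict in counts:
            lines.append(f"  {verdict:16s} {int(counts[verdict])}")
    anomalies = report.verdicts[report.verdicts["verdict"].isin(("swap", "mixture"))]
    if len(anomalies):
        lines.append("")
        lines.append("anomalies:")
        for row in anomalies.itertuples(index=False):
            if row.verdict == "swap":
                lines.append(
                    f"  {row.microbiome_id}: swap, closest genomic sample "
                    f"{row.argmin_id} (d={row.min_distance:.4f}, self d={row.self_distance:.4f})"
                )
            else:
                lines.append(
                    f"  {row.microbiome_id}: mixture with {row.contaminant_id} "
                    f"(p={row.p_hat:.3f}, eps={row.eps_hat:.4f}, LRT={row.lrt:.3g})"
                )
    if report.metadata.get("scan_failures"):
        lines.append("")
        lines.append(f"scan failures: {report.metadata['scan_failures']}")
    return "\n".join(lines) + "\n"
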