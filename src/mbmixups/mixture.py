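"""Two-sample mixture model for contamination in host-read allele counts.

A microbiome sample suspected of contamination is modeled as a mixture of the
correctly labeled individual and a single contaminant: a proportion p of the
host DNA comes from the contaminant, and reads carry the wrong allele with
sequencing error rate eps.  For a read at a SNP where the labeled sample has
minor-allele frequency f1 = dosage/2 and the candidate contaminant f2, the
chance of observing the minor allele is

    Pr(B) = eps + f* (1 - 2 eps),    f* = (1 - p) f1 + p f2.

Conditional on the per-cell read totals of a 3x3x2 joint category table, the
multinomial likelihood over the 18 outcomes factorizes into nine independent
binomials (one per joint-genotype cell), which is the form implemented here:
the MLEs are identical and the numerics simpler.  The likelihood-ratio test
statistic for no contamination (p = 0) is twice the log-likelihood difference
between the full fit and the constrained fit with only eps free.

Across a cohort, each candidate contaminant is fit in turn; because the LRT
is nominally significant almost everywhere at these read depths (a weakness
of the binomial read model, which ignores overdispersion), a contaminant is
called only when its LRT separates from all other candidates by a large
factor, not by LRT calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit, xlogy

from .counts import JointCategoryTable, SnpAlleleCounts, tabulate_pair
from .genotypes import GENOTYPE_LABELS, GenotypeMatrix

log = logging.getLogger(__name__)

#: Minor-allele frequency implied by each genotype (index = dosage).
_DOSE_FREQ = np.array([0.0, 0.5, 1.0])

_GT_TO_DOSE = {g: i for i, g in enumerate(GENOTYPE_LABELS)}

NEG_INF = float("-inf")


def _as_freq(g) -> np.ndarray:
    """Genotype argument (label, dosage, or array thereof) -> minor-allele frequency."""
    arr = np.asarray(g)
    if arr.dtype.kind in "US":
        doses = np.vectorize(_GT_TO_DOSE.__getitem__)(arr)
    else:
        doses = arr.astype(np.int64)
        if not np.isin(doses, (0, 1, 2)).all():
            raise ValueError(f"genotype dosage out of range: {g!r}")
    return _DOSE_FREQ[doses]


def _check_params(p: float, eps: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"contaminant proportion p={p} outside [0, 1]")
    if not (0.0 <= eps < 0.5):
        raise ValueError(f"error rate eps={eps} outside [0, 0.5)")


def expected_minor_prob(g_self, g_other, p: float, eps: float):
    """Probability that a read carries the minor (B) allele.

    ``g_self``/``g_other`` may be genotype labels ("AA"/"AB"/"BB"), dosages
    (0/1/2), or arrays of either.  With f(g) the minor-allele frequency of a
    genotype, the mixture frequency is f* = (1-p) f(g_self) + p f(g_other)
    and the read-level probability is eps + f* (1 - 2 eps).
    """
    _check_params(p, eps)
    f_star = (1.0 - p) * _as_freq(g_self) + p * _as_freq(g_other)
    out = eps + f_star * (1.0 - 2.0 * eps)
    return float(out) if np.isscalar(out) or out.shape == () else out


def _cell_probs(p: float, eps: float) -> np.ndarray:
    """3x3 matrix of minor-read probabilities over joint-genotype cells."""
    f_star = (1.0 - p) * _DOSE_FREQ[:, None] + p * _DOSE_FREQ[None, :]
    return eps + f_star * (1.0 - 2.0 * eps)


def mixture_loglik(t: JointCategoryTable | np.ndarray, p: float, eps: float) -> float:
    """Binomial log-likelihood of a joint category table (constants dropped).

    Sums n_B log pi + n_A log(1 - pi) over the nine joint-genotype cells.
    The dropped binomial coefficients are identical under the null and
    alternative, so likelihood ratios are unaffected.  A probability of
    exactly 0 or 1 contradicted by a positive count yields -inf.
    """
    _check_params(p, eps)
    counts = t.counts if isinstance(t, JointCategoryTable) else np.asarray(t)
    pi = _cell_probs(p, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(counts[:, :, 1], pi) + xlogy(counts[:, :, 0], 1.0 - pi)
    total = ll.sum()
    return float(total) if np.isfinite(total) else NEG_INF


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of the two-parameter mixture model."""

    microbiome_id: str
    genomic_id_self: str
    genomic_id_other: str
    p_hat: float
    eps_hat: float
    eps0_hat: float
    loglik_alt: float
    loglik_null: float
    lrt: float
    n_reads: int
    identifiable: bool = True
    converged: bool = True


def _null_eps_closed_form(counts: np.ndarray) -> float:
    """Closed-form null MLE of eps: pooled discordance at homozygous-self rows.

    Under p = 0 the minor-read probability is eps at AA rows, 1 - eps at BB
    rows and 1/2 (free of eps) at AB rows, so the MLE is the discordant
    fraction among homozygous-row reads.
    """
    by_self = counts.sum(axis=1)  # 3x2
    disc = by_self[0, 1] + by_self[2, 0]
    tot = by_self[0].sum() + by_self[2].sum()
    return float(disc / tot) if tot > 0 else 0.0


_EPS_LO, _EPS_HI = 1e-12, 0.5 - 1e-9


def _fit_null(counts: np.ndarray) -> tuple[float, float]:
    """Numerically maximize the p = 0 likelihood over eps.

    A 1-D bounded search; the closed-form pooled-discordance estimate is
    evaluated as well and the better of the two is returned.
    """
    def nll(eps: float) -> float:
        return -mixture_loglik(counts, 0.0, eps)

    res = minimize_scalar(nll, bounds=(_EPS_LO, _EPS_HI), method="bounded")
    candidates = [(float(res.x), -float(res.fun))]
    eps_cf = min(max(_null_eps_closed_form(counts), _EPS_LO), _EPS_HI)
    candidates.append((eps_cf, mixture_loglik(counts, 0.0, eps_cf)))
    eps_best, ll_best = max(candidates, key=lambda c: c[1])
    return eps_best, ll_best


def _moment_estimates(counts: np.ndarray, eps0: float) -> tuple[float, float]:
    """Rough (p, eps) from the most informative cells.

    The minor-read fraction in the (AA, BB) cell and the major-read fraction
    in the (BB, AA) cell each estimate eps + p(1 - 2 eps) ~ p; pooled they
    seed the optimizer.
    """
    disc = counts[0, 2, 1] + counts[2, 0, 0]
    tot = counts[0, 2].sum() + counts[2, 0].sum()
    if tot == 0:
        return 0.5, eps0
    frac = disc / tot
    denom = 1.0 - 2.0 * eps0
    p_m = (frac - eps0) / denom if denom > 0 else frac
    return float(np.clip(p_m, 1e-4, 1.0 - 1e-4)), eps0


def fit_mixture(t: JointCategoryTable) -> MixtureFit:
    """MLEs of (p, eps), the null fit, and the LRT for p = 0.

    The alternative is maximized on an unconstrained scale (logit of p,
    logit of 2 eps) by Nelder-Mead from five starting points, including
    moment estimates from the discordant-homozygous cells; the best result
    is kept.  The null fixes p = 0 and maximizes over eps alone.

    If no reads fall in a cell where the two genotypes imply different
    allele frequencies, p is unidentifiable: the null fit is returned with
    p_hat = 0, lrt = 0 and ``identifiable=False``.
    """
    counts = t.counts
    n_reads = int(counts.sum())
    ids = (t.microbiome_id, t.genomic_id_self, t.genomic_id_other)

    if n_reads == 0:
        return MixtureFit(*ids, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, identifiable=False)

    eps0, ll_null = _fit_null(counts)

    freq_diff = _DOSE_FREQ[:, None] != _DOSE_FREQ[None, :]
    informative = int(counts.sum(axis=2)[freq_diff].sum())
    if informative == 0:
        log.warning(
            "mixture fit %s vs %s: p unidentifiable (no reads at "
            "genotype-discordant SNPs)", ids[1], ids[2],
        )
        return MixtureFit(
            *ids, 0.0, eps0, eps0, ll_null, ll_null, 0.0, n_reads,
            identifiable=False,
        )

    def nll(x: np.ndarray) -> float:
        p = expit(x[0])
        eps = min(0.5 * expit(x[1]), _EPS_HI)  # expit saturates at 1.0 in float
        ll = mixture_loglik(counts, p, eps)
        return -ll if np.isfinite(ll) else 1e300

    eps0_c = float(np.clip(eps0, 1e-6, 0.4999))
    p_m, _ = _moment_estimates(counts, eps0)
    starts = [
        (p_m, eps0_c),
        (0.01, 0.005),
        (1e-4, eps0_c),
        (0.5, eps0_c),
        (0.99, eps0_c),
    ]
    best = None
    any_converged = False
    for p0, e0 in starts:
        x0 = np.array([logit(np.clip(p0, 1e-6, 1 - 1e-6)), logit(np.clip(2 * e0, 1e-9, 1 - 1e-9))])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"mixture optimizer failed for {ids[1]} vs {ids[2]}: no finite optimum"
        )
    if not any_converged:
        raise RuntimeError(
            f"mixture optimizer did not converge for {ids[1]} vs {ids[2]}: {best.message}"
        )
    p_hat = float(expit(best.x[0]))
    eps_hat = float(0.5 * expit(best.x[1]))
    ll_alt = -float(best.fun)
    if ll_alt < ll_null:  # the null is nested; never report a worse optimum
        p_hat, eps_hat, ll_alt = 0.0, eps0, ll_null
    lrt = 2.0 * (ll_alt - ll_null)
    if lrt < -1e-6:
        raise RuntimeError(f"negative LRT {lrt} for {ids[1]} vs {ids[2]}")
    lrt = max(lrt, 0.0)
    return MixtureFit(
        *ids, p_hat, eps_hat, eps0, ll_alt, ll_null, lrt, n_reads,
        identifiable=True, converged=True,
    )


# ---------------------------------------------------------------------------
# Cohort scan
# ---------------------------------------------------------------------------

@dataclass
class ContaminantScan:
    """Mixture fits of one microbiome sample against every candidate contaminant.

    ``results`` is sorted by descending LRT.  ``flagged_contaminant`` and
    ``separation`` are filled in by :func:`detect_contaminant`.
    """

    microbiome_id: str
    genomic_id_self: str
    results: pd.DataFrame
    fits: dict[str, MixtureFit] = field(default_factory=dict)
    flagged_contaminant: str | None = None
    separation: float = float("nan")


def scan_contaminants(
    reads: SnpAlleleCounts,
    geno: GenotypeMatrix,
    id_self: str,
    candidates: Sequence[str] | None = None,
) -> ContaminantScan:
    """Fit the mixture model against each candidate contaminant in turn.

    ``candidates`` defaults to every genotyped sample other than ``id_self``.
    Unidentifiable candidates are recorded with a flag, not dropped.
    """
    if id_self not in geno.calls.index:
        raise KeyError(f"unknown genotyped sample {id_self!r}")
    if candidates is None:
        candidates = [s for s in geno.sample_ids if s != id_self]
    fits = {}
    for cand in candidates:
        table = tabulate_pair(reads, geno, id_self, cand)
        fits[cand] = fit_mixture(table)
    frame = pd.DataFrame(
        {
            "candidate_id": list(fits),
            "p_hat": [f.p_hat for f in fits.values()],
            "eps_hat": [f.eps_hat for f in fits.values()],
            "lrt": [f.lrt for f in fits.values()],
            "n_reads": [f.n_reads for f in fits.values()],
            "identifiable": [f.identifiable for f in fits.values()],
        }
    ).sort_values("lrt", ascending=False, kind="stable").reset_index(drop=True)
    return ContaminantScan(reads.sample_id, id_self, frame, fits)


def boundary_lrt_critical(n_candidates: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted critical value of the boundary-null LRT.

    Under the null, p = 0 lies on the parameter boundary and the LRT is a
    50:50 mixture of a point mass at 0 and a chi-square with 1 df, so the
    per-candidate tail probability of L is sf(L)/2; requiring a family-wise
    level ``alpha`` over ``n_candidates`` candidates gives the chi-square(1)
    upper quantile at 2 alpha / n_candidates.
    """
    from scipy.stats import chi2

    return float(chi2.isf(min(2.0 * alpha / n_candidates, 1.0), 1))


def detect_contaminant(
    scan: ContaminantScan,
    gap_factor: float = 10.0,
    min_lrt: float | None = None,
) -> tuple[str | None, float]:
    """Separation rule: flag the top candidate only if it stands apart.

    With L1 >= L2 the two largest LRT values in the scan, the top candidate
    is flagged iff L1 / L2 >= ``gap_factor`` and L1 >= ``min_lrt``.  The
    separation statistic L1 / L2 is reported regardless (inf when
    L2 = 0 < L1, NaN when L1 = 0).  The scan object is annotated in place
    and (flagged_id, separation) is returned.

    ``min_lrt`` guards the degenerate case of an otherwise-null scan in
    which one candidate draws a small but nonzero LRT while the rest sit at
    or near the boundary: the ratio alone would misread that as separation.
    The default (None) uses :func:`boundary_lrt_critical` over the scan's
    candidates; at realistic read depths any genuine contaminant's LRT is
    orders of magnitude larger, so the floor only suppresses no-evidence
    scans.
    """
    lrts = scan.results["lrt"].to_numpy()
    if len(lrts) < 2:
        raise ValueError("separation rule needs at least two candidates")
    if min_lrt is None:
        min_lrt = boundary_lrt_critical(len(lrts))
    l1, l2 = lrts[0], lrts[1]
    if l1 <= 0:
        separation = float("nan")
        flagged = None
    else:
        separation = float("inf") if l2 == 0 else float(l1 / l2)
        flagged = (
            str(scan.results["candidate_id"].iloc[0])
            if separation >= gap_factor and l1 >= min_lrt
            else None
        )
    scan.flagged_contaminant = flagged
    scan.separation = separation
    return flagged, separation


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_scan(scan: ContaminantScan, ax=None):
    """LRT vs estimated contaminant proportion, one point per candidate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    r = scan.results
    ax.scatter(r["p_hat"], r["lrt"], s=14, color="#555555")
    if scan.flagged_contaminant is not None:
        top = r[r["candidate_id"] == scan.flagged_contaminant]
        ax.scatter(top["p_hat"], top["lrt"], s=50, color="#d81b60",
                   label=scan.flagged_contaminant, zorder=3)
        ax.legend(fontsize=8)
    ax.set_xlabel("estimated contaminant proportion")
    ax.set_ylabel("LRT statistic")
    ax.set_title(scan.microbiome_id)
    return ax


def plot_cohort_lrt(summary: pd.DataFrame, ax=None, log_scale: bool = True):
    """Cohort view: per-sample maximum LRT vs the matching p estimate.

    ``summary`` needs columns p_hat, lrt, and optionally verdict (colors).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if "verdict" in summary.columns:
        for verdict, grp in summary.groupby("verdict"):
            ax.scatter(grp["p_hat"], grp["lrt"], s=18, label=f"{verdict} (n={len(grp)})",
                       alpha=0.8)
        ax.legend(fontsize=8)
    else:
        ax.scatter(summary["p_hat"], summary["lrt"], s=18, color="#555555")
    if log_scale and (summary["lrt"] > 0).any():
        ax.set_yscale("log")
    ax.set_xlabel("estimated contaminant proportion")
    ax.set_ylabel("maximum LRT statistic")
    return ax
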