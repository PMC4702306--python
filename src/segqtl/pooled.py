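"""Pooled-segregant (bulk segregant) QTL mapping.

The pooled engine works on read counts from a pool of phenotype-selected
segregants.  At each SNP distinguishing the parents, the variant frequency
is the fraction of reads carrying the superior parent's allele; under
random (Mendelian) segregation it is 0.5, and sustained deviation marks
linkage to the trait.  Steps: quality filtering (coverage >= 15, PHRED >=
35 by default), per-marker variant frequency, kernel smoothing on the logit
scale with a confidence band, calling maximal regions whose band excludes
0.5, an exact binomial linkage test for individually scored SNPs, and
subtraction of linkage seen in an unselected control pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .counts import AlleleCountMatrix
from .intervals import QTLInterval, subtract_unselected  # noqa: F401  (re-export)

DEFAULT_MIN_COVERAGE = 15
DEFAULT_MIN_QUALITY = 35.0
DEFAULT_BANDWIDTH = 20_000.0


def quality_filter(
    counts: AlleleCountMatrix,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> AlleleCountMatrix:
    """Mask marker/sample cells below the coverage or base-quality cutoffs.

    Thresholds are inclusive: coverage 15 with quality 35 is retained.
    Ordering is preserved; nothing is dropped, only masked.
    """
    if min_coverage < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    cov = counts.coverage()
    mask = counts.mask | (cov < min_coverage) | (counts.qual < min_quality)
    return counts.with_mask(mask)


def variant_frequency(counts: AlleleCountMatrix, sample: str) -> pd.DataFrame:
    """SNP variant-frequency series for one sample.

    f = superior count / total reads, in [0, 1]; NaN where the cell is
    masked or uncovered.  Columns: chrom, pos, f, coverage.
    """
    sup, inf, _, mask = counts.column(sample)
    cov = (sup + inf).astype(float)
    usable = (~mask) & (cov > 0)
    f = np.full(len(cov), np.nan)
    f[usable] = sup[usable] / cov[usable]
    cov = np.where(usable, cov, 0.0)
    return pd.DataFrame(
        {
            "chrom": counts.markers["chrom"].to_numpy(),
            "pos": counts.markers["pos"].to_numpy(),
            "f": f,
            "coverage": cov,
        }
    )


@dataclass
class SmoothedCurve:
    """Kernel-smoothed variant-frequency curve with a confidence band.

    One row per covered marker: fitted frequency, logit-scale standard
    error, and the band at the fitting ``alpha``.  ``se_logit`` lets the
    band be re-formed at any other level without re-smoothing.
    """

    data: pd.DataFrame  # chrom, pos, fit, se_logit, lo, hi
    bandwidth: float
    alpha: float
    n_pool: int | None = None


def smooth_frequencies(
    series: pd.DataFrame,
    bandwidth: float = DEFAULT_BANDWIDTH,
    alpha: float = 0.05,
    n_pool: int | None = None,
    block: int = 1024,
) -> SmoothedCurve:
    """Kernel-weighted local binomial fit of the variant frequency.

    Per chromosome, at each covered marker the neighbouring markers' read
    counts are combined with Gaussian kernel weights (sd = ``bandwidth``
    bp); the fitted frequency is the weighted success fraction (with a
    half-read continuity correction keeping it inside (0, 1)) and the
    confidence band is a normal approximation on the logit scale using the
    Kish effective number of reads.  Constant input gives a constant fit;
    as bandwidth grows the fit approaches the coverage-weighted mean.

    ``n_pool`` is the number of segregants in the pool.  Pooled reads are a
    two-stage sample — first the pool's segregant composition, then reads
    from it — and the composition stage is shared by all markers of a
    linkage block, so smoothing cannot average it away.  When given, the
    effective trial count is capped accordingly:
    1/n_eff = 1/n_reads_eff + 1/n_pool.  Without it the band covers read
    noise only (appropriate for per-segregant series).
    """
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for chrom, grp in series.dropna(subset=["f"]).groupby("chrom", sort=False):
        x = grp["pos"].to_numpy(dtype=float)
        tot = grp["coverage"].to_numpy(dtype=float)
        succ = grp["f"].to_numpy() * tot
        n = len(x)
        if n == 0:
            continue
        fit = np.empty(n)
        se = np.empty(n)
        for lo_i in range(0, n, block):
            hi_i = min(lo_i + block, n)
            d = x[lo_i:hi_i, None] - x[None, :]
            w = np.exp(-0.5 * (d / bandwidth) ** 2)
            S = w @ succ
            N = w @ tot
            p = (S + 0.5) / (N + 1.0)
            n_eff = N**2 / (w**2 @ tot)
            if n_pool is not None:
                n_eff = 1.0 / (1.0 / n_eff + 1.0 / n_pool)
            fit[lo_i:hi_i] = p
            se[lo_i:hi_i] = 1.0 / np.sqrt(n_eff * p * (1 - p))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "fit": fit,
                    "se_logit": se,
                    "lo": expit(logit(fit) - z * se),
                    "hi": expit(logit(fit) + z * se),
                }
            )
        )
    data = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "pos", "fit", "se_logit", "lo", "hi"])
    )
    return SmoothedCurve(data=data, bandwidth=bandwidth, alpha=alpha, n_pool=n_pool)


@dataclass
class LinkageTestResult:
    """Exact two-sided binomial test of a SNP's segregation against 0.5."""

    k: int
    n: int
    pvalue: float
    direction: str  # superior | inferior | none


def binomial_linkage_test(k: int, n: int) -> LinkageTestResult:
    """Exact two-sided binomial p-value under the Mendelian null p=0.5.

    The p-value sums the probabilities of all outcomes no more likely than
    the observed k (the standard exact two-sided construction).
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not (0 <= k <= n):
        raise ValueError("successes out of range")
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    direction = "superior" if k * 2 > n else ("inferior" if k * 2 < n else "none")
    return LinkageTestResult(k=k, n=n, pvalue=float(p), direction=direction)


def call_qtl_intervals(curve: SmoothedCurve, alpha: float = 0.05) -> list[QTLInterval]:
    """Maximal runs of markers whose confidence band excludes 0.5.

    Boundaries are the first and last covered marker of the run (marker
    anchored); the peak is the marker with the most extreme fitted value;
    direction follows the side of 0.5.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    out: list[QTLInterval] = []
    for chrom, grp in curve.data.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        fit = grp["fit"].to_numpy()
        lo = expit(logit(fit) - z * grp["se_logit"].to_numpy())
        hi = expit(logit(fit) + z * grp["se_logit"].to_numpy())
        state = np.where(lo > 0.5, 1, np.where(hi < 0.5, -1, 0))
        for s, e in _runs(state):
            seg_fit = fit[s:e]
            if state[s] > 0:
                peak_i = s + int(np.argmax(seg_fit))
                direction = "superior"
            else:
                peak_i = s + int(np.argmin(seg_fit))
                direction = "inferior"
            out.append(
                QTLInterval(
                    chrom=chrom,
                    start=int(pos[s]),
                    end=int(pos[e - 1]),
                    peak=int(pos[peak_i]),
                    direction=direction,
                    tier="pooled",
                    peak_value=float(fit[peak_i]),
                )
            )
    return out


def _runs(state: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of identical nonzero state."""
    runs = []
    start = None
    for i, v in enumerate(state):
        if v != 0 and (start is None or state[start] != v):
            if start is not None and state[start] != 0:
                runs.append((start, i))
            start = i
        elif v == 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(state)))
    return runs


def map_pool(
    counts: AlleleCountMatrix,
    sample: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_quality: float = DEFAULT_MIN_QUALITY,
    bandwidth: float = DEFAULT_BANDWIDTH,
    alpha: float = 0.05,
    n_pool: int | None = None,
) -> tuple[pd.DataFrame, SmoothedCurve, list[QTLInterval]]:
    """Full pooled pipeline: filter -> frequency -> smooth -> call."""
    filtered = quality_filter(counts, min_coverage, min_quality)
    freq = variant_frequency(filtered, sample)
    curve = smooth_frequencies(freq, bandwidth=bandwidth, alpha=alpha, n_pool=n_pool)
    return freq, curve, call_qtl_intervals(curve, alpha=alpha)
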