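"""Individual-segregant QTL mapping via Kullback-Leibler parent-of-origin calls.

Each sequenced segregant is compared SNP-by-SNP with both parental strains:
read counts become genotype distributions over the two parental alleles
(with a pseudocount), and the KL divergence of the segregant's distribution
to each parent decides the parent of origin.  Assignments are filtered at a
conservative FDR (default 0.007, i.e. correcting each of the samples
separately), the signed divergence scores are Gaussian-smoothed along each
chromosome to damp sequencing error, summed in non-overlapping 3-kb windows
into a ternary {+1, -1, 0} parent-of-origin track, and the tracks of the
top-k phenotype-ranked segregants are averaged.  Window averages above +0.7
(or below -0.7) mark non-random segregation and are called as QTL intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import AlleleCountMatrix
from .genome import GenomeLayout
from .intervals import QTLInterval
from .pooled import binomial_linkage_test

DEFAULT_FDR = 0.007
DEFAULT_SIGMA = 1000.0
DEFAULT_WINDOW = 3000
DEFAULT_AVG_THRESHOLD = 0.7


def genotype_distribution(sup: np.ndarray, inf: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Pseudocounted genotype distribution over the two parental alleles.

    p(allele) = (count + alpha) / (total + 2 alpha); shape (..., 2) with the
    superior allele first.  Zero coverage yields the uninformative (0.5,
    0.5).
    """
    if alpha <= 0:
        raise ValueError("pseudocount must be positive")
    sup = np.asarray(sup, dtype=float)
    inf = np.asarray(inf, dtype=float)
    tot = sup + inf + 2 * alpha
    return np.stack([(sup + alpha) / tot, (inf + alpha) / tot], axis=-1)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """D(p || q) in nats, elementwise over the last axis (the 2-simplex)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return terms.sum(axis=-1)


@dataclass
class DivergenceRecord:
    """Per-SNP parent-of-origin evidence for one segregant.

    ``signed`` = D(seg || inferior) - D(seg || superior): positive when the
    segregant's genotype distribution is closer to the superior parent.
    ``assignment`` is +1 (superior), -1 (inferior) or 0 (undetermined);
    ``pvalue`` is the probability of read counts at least this supportive
    of the assignment if the SNP actually came from the other parent and
    the assigned-allele reads were sequencing errors.
    """

    d_superior: np.ndarray
    d_inferior: np.ndarray
    signed: np.ndarray
    assignment: np.ndarray
    pvalue: np.ndarray


def kl_assign(
    seg: np.ndarray,
    parent_sup: np.ndarray,
    parent_inf: np.ndarray,
    sup_counts: np.ndarray | None = None,
    inf_counts: np.ndarray | None = None,
    error_rate: float = 0.002,
) -> DivergenceRecord:
    """Assign parent of origin per SNP by smaller KL divergence.

    ``seg``/``parent_*`` are (n, 2) genotype distributions.  When raw read
    counts are supplied, an assignment p-value is computed from the exact
    binomial tail of the assigned-allele count under the non-assigned
    parent's error model (assigned allele arises only with ``error_rate``).
    """
    d_sup = kl_divergence(seg, parent_sup)
    d_inf = kl_divergence(seg, parent_inf)
    signed = d_inf - d_sup
    assignment = np.sign(signed).astype(np.int8)
    pvalue = np.ones_like(d_sup)
    if sup_counts is not None and inf_counts is not None:
        n = np.asarray(sup_counts) + np.asarray(inf_counts)
        k_assigned = np.where(assignment > 0, sup_counts, inf_counts)
        det = assignment != 0
        pvalue[det] = stats.binom.sf(k_assigned[det] - 1, n[det], error_rate)
        pvalue = np.clip(pvalue, 0.0, 1.0)
    return DivergenceRecord(d_sup, d_inf, signed, assignment, pvalue)


def fdr_filter(record: DivergenceRecord, q: float = DEFAULT_FDR) -> DivergenceRecord:
    """Benjamini-Hochberg filter of one segregant's assignments.

    Step-up at level ``q`` over the determined SNPs; assignments that fail
    become undetermined and their signed scores are zeroed, so downstream
    smoothing and window sums see no evidence there.  A p-value exactly at
    its step-up threshold is retained.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    det = record.assignment != 0
    assignment = record.assignment.copy()
    signed = record.signed.copy()
    if det.any():
        reject, _, _, _ = multipletests(record.pvalue[det], alpha=q, method="fdr_bh")
        idx = np.flatnonzero(det)[~reject]
        assignment[idx] = 0
        signed[idx] = 0.0
    return DivergenceRecord(
        record.d_superior, record.d_inferior, signed, assignment, record.pvalue
    )


def gaussian_smooth(
    positions: np.ndarray, scores: np.ndarray, sigma: float = DEFAULT_SIGMA, block: int = 1024
) -> np.ndarray:
    """Gaussian kernel smoothing of scores in genomic coordinates.

    Kernel-weighted average over the observed SNP positions of one
    chromosome (weights exp(-(dx)^2 / 2 sigma^2), row-normalised), so a
    constant series is returned unchanged and an interior impulse on a
    regular grid conserves its mass.  ``scores`` may be (n,) or (n, m) to
    smooth many segregants over shared positions at once.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(positions, dtype=float)
    s = np.asarray(scores, dtype=float)
    out = np.empty_like(s)
    n = len(x)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        w = np.exp(-0.5 * ((x[lo:hi, None] - x[None, :]) / sigma) ** 2)
        denom = w.sum(axis=1)
        num = w @ s
        out[lo:hi] = num / (denom[:, None] if s.ndim > 1 else denom)
    return out


@dataclass
class ParentOfOriginTrack:
    """Ternary {+1, -1, 0} window calls tiling the genome for one segregant."""

    layout: GenomeLayout
    window: int
    calls: dict[str, np.ndarray]  # chrom -> int8 array, one value per tile

    def window_starts(self, chrom: str) -> np.ndarray:
        return 1 + self.window * np.arange(len(self.calls[chrom]))


def window_calls(
    layout: GenomeLayout,
    chroms: np.ndarray,
    positions: np.ndarray,
    smoothed: np.ndarray,
    window: int = DEFAULT_WINDOW,
    tau: float = 0.0,
) -> ParentOfOriginTrack:
    """Sum smoothed signed scores in non-overlapping windows, call the sign.

    Windows tile each chromosome from position 1; a window sum strictly
    above ``tau`` calls +1 (superior), strictly below ``-tau`` calls -1,
    anything else (including windows without surviving SNPs) is 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    calls: dict[str, np.ndarray] = {}
    chroms = np.asarray(chroms)
    for chrom in layout.names:
        n_win = int(np.ceil(layout.length_of(chrom) / window))
        sums = np.zeros(n_win)
        on = chroms == chrom
        if on.any():
            idx = ((np.asarray(positions)[on] - 1) // window).astype(int)
            np.add.at(sums, idx, np.asarray(smoothed, dtype=float)[on])
        calls[chrom] = np.where(sums > tau, 1, np.where(sums < -tau, -1, 0)).astype(np.int8)
    return ParentOfOriginTrack(layout=layout, window=window, calls=calls)


@dataclass
class AveragedLinkageTrack:
    """Mean ternary track over the k top-ranked segregants; values in [-1, 1]."""

    layout: GenomeLayout
    window: int
    k: int
    values: dict[str, np.ndarray]

    def window_starts(self, chrom: str) -> np.ndarray:
        return 1 + self.window * np.arange(len(self.values[chrom]))


def phenotype_ordered_average(
    tracks: list[ParentOfOriginTrack], ranking: np.ndarray, k: int
) -> AveragedLinkageTrack:
    """Average the ternary tracks of the k most tolerant segregants.

    ``ranking`` lists track indices from most to least extreme phenotype;
    QTLs supported only in the most tolerant segregants fade as k grows.
    """
    if not (1 <= k <= len(tracks)):
        raise ValueError("k out of range")
    chosen = [tracks[int(i)] for i in np.asarray(ranking)[:k]]
    first = chosen[0]
    values = {
        chrom: np.mean([t.calls[chrom] for t in chosen], axis=0)
        for chrom in first.layout.names
    }
    return AveragedLinkageTrack(layout=first.layout, window=first.window, k=k, values=values)


def call_qtls_from_average(
    avg: AveragedLinkageTrack, threshold: float = DEFAULT_AVG_THRESHOLD
) -> list[QTLInterval]:
    """Runs of windows with |average| strictly above the threshold.

    Adjacent qualifying windows of the same direction merge into one
    interval; a window exactly at the threshold is not called.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out: list[QTLInterval] = []
    for chrom in avg.layout.names:
        v = avg.values[chrom]
        starts = avg.window_starts(chrom)
        length = avg.layout.length_of(chrom)
        state = np.where(v > threshold, 1, np.where(v < -threshold, -1, 0))
        i = 0
        while i < len(state):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < len(state) and state[j] == state[i]:
                j += 1
            seg = v[i:j]
            peak_i = i + int(np.argmax(seg) if state[i] > 0 else np.argmin(seg))
            out.append(
                QTLInterval(
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(min(starts[j - 1] + avg.window - 1, length)),
                    peak=int(starts[peak_i] + avg.window // 2),
                    direction="superior" if state[i] > 0 else "inferior",
                    tier="individual",
                    peak_value=float(seg.max() if state[i] > 0 else seg.min()),
                )
            )
            i = j
    return out


@lru_cache(maxsize=4096)
def _binom_p(k: int, n: int) -> float:
    return binomial_linkage_test(k, n).pvalue


def per_snp_binomial_pvalues(assignments: np.ndarray, markers: pd.DataFrame) -> pd.DataFrame:
    """Exact binomial p per SNP from determined assignments across segregants.

    ``assignments`` is (n_snps, n_segregants) with values {+1, -1, 0};
    trials = determined calls, successes = superior calls, null 0.5.  SNPs
    with no determined call are omitted.
    """
    A = np.asarray(assignments)
    n = (A != 0).sum(axis=1)
    k = (A > 0).sum(axis=1)
    keep = n > 0
    pvals = np.array([_binom_p(int(ki), int(ni)) for ki, ni in zip(k[keep], n[keep])])
    return pd.DataFrame(
        {
            "chrom": markers["chrom"].to_numpy()[keep],
            "pos": markers["pos"].to_numpy()[keep],
            "k": k[keep],
            "n": n[keep],
            "pvalue": pvals,
        }
    )


def map_individuals(
    counts: AlleleCountMatrix,
    parent_counts: AlleleCountMatrix,
    layout: GenomeLayout,
    ranking: np.ndarray | None = None,
    k: int | None = None,
    pseudocount: float = 1.0,
    error_rate: float = 0.002,
    fdr_q: float = DEFAULT_FDR,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_AVG_THRESHOLD,
) -> tuple[list[ParentOfOriginTrack], np.ndarray, AveragedLinkageTrack, list[QTLInterval]]:
    """Full individual pipeline for a set of sequenced segregants.

    Returns the per-segregant ternary tracks, the (n_snps x n_segregants)
    post-FDR assignment matrix, the phenotype-ordered average over the top
    ``k`` (default: all, in given sample order) and the called intervals.
    """
    p_sup = genotype_distribution(*parent_counts.column("superior")[:2], alpha=pseudocount)
    p_inf = genotype_distribution(*parent_counts.column("inferior")[:2], alpha=pseudocount)
    markers = counts.markers
    chroms = markers["chrom"].to_numpy()
    positions = markers["pos"].to_numpy()
    tracks: list[ParentOfOriginTrack] = []
    assignments = np.zeros((counts.n_markers, len(counts.samples)), dtype=np.int8)
    signed_cols = np.zeros((counts.n_markers, len(counts.samples)))
    for j, sample in enumerate(counts.samples):
        sup, inf, _, mask = counts.column(sample)
        seg = genotype_distribution(sup, inf, alpha=pseudocount)
        rec = kl_assign(seg, p_sup, p_inf, sup, inf, error_rate=error_rate)
        # masked cells carry no evidence
        rec.assignment[mask] = 0
        rec.signed[mask] = 0.0
        rec = fdr_filter(rec, q=fdr_q)
        assignments[:, j] = rec.assignment
        signed_cols[:, j] = rec.signed
    # shared positions: smooth all segregants per chromosome in one pass
    smoothed = np.empty_like(signed_cols)
    for chrom in layout.names:
        on = chroms == chrom
        if on.any():
            smoothed[on] = gaussian_smooth(positions[on], signed_cols[on], sigma=sigma)
    for j in range(len(counts.samples)):
        tracks.append(
            window_calls(layout, chroms, positions, smoothed[:, j], window=window)
        )
    if ranking is None:
        ranking = np.arange(len(tracks))
    if k is None:
        k = len(tracks)
    avg = phenotype_ordered_average(tracks, ranking, k)
    return tracks, assignments, avg, call_qtls_from_average(avg, threshold=threshold)
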