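"""Synthetic cross, inbreeding, selection and sequencing simulator.

Emulates the experimental design behind pooled-segregant QTL mapping in
yeast: two haploid parents differing at tens of thousands of SNPs are
crossed; the hybrid is sporulated to give F1 segregants; optional rounds of
random-spore mass-mating inbreeding give advanced (e.g. F7) segregants; a
polygenic phenotype with noise is assigned; truncation selection retains the
best segregants; and pooled or individual short-read allele counts are drawn
with configurable depth and base-error models.

Crossovers follow a Poisson model without interference: per bivalent the
crossover count is Poisson with mean twice the chromosome's genetic length
in Morgans, positions uniform, each crossover resolved on one of the two
chromatid pairs, so every tetrad consists of two complementary spore pairs
and carries exactly two copies of each parental allele at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng, substream
from .counts import AlleleCountMatrix
from .genome import INFERIOR, SUPERIOR, GenomeLayout, HaplotypeMosaic, _merge_adjacent

Diploid = tuple[HaplotypeMosaic, HaplotypeMosaic]


# ---------------------------------------------------------------------------
# parental markers


def make_parental_markers(layout: GenomeLayout, n_markers: int, seed: int) -> pd.DataFrame:
    """Scatter ``n_markers`` biallelic SNPs uniformly over the genome.

    Returns a frame with columns ``chrom, pos, superior_allele,
    inferior_allele``, sorted by (chromosome, position), positions unique
    within each chromosome.  Marker counts per chromosome are multinomial in
    proportion to physical length; positions are drawn without replacement.
    """
    if n_markers < 0:
        raise ValueError("n_markers must be non-negative")
    if n_markers > layout.total_length:
        raise ValueError("more markers requested than assignable positions")
    rng = as_rng(seed, "markers")
    lengths = np.array(layout.lengths, dtype=float)
    per_chrom = rng.multinomial(n_markers, lengths / lengths.sum())
    # redistribute overflow from chromosomes too short for their draw
    for _ in range(len(per_chrom)):
        over = per_chrom - np.array(layout.lengths)
        if (over <= 0).all():
            break
        i = int(np.argmax(over))
        room = np.array(layout.lengths) - per_chrom
        j = int(np.argmax(room))
        move = min(over[i], room[j])
        per_chrom[i] -= move
        per_chrom[j] += move

    bases = "ACGT"
    rows = []
    for chrom, length, k in zip(layout.names, layout.lengths, per_chrom):
        pos = np.sort(rng.choice(length, size=int(k), replace=False) + 1)
        sup_idx = rng.integers(0, 4, size=int(k))
        inf_idx = (sup_idx + rng.integers(1, 4, size=int(k))) % 4
        for p, a, b in zip(pos, sup_idx, inf_idx):
            rows.append((chrom, int(p), bases[a], bases[b]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "superior_allele", "inferior_allele"])
    return df.reset_index(drop=True)


def genotype_matrix(segregants: list[HaplotypeMosaic], markers: pd.DataFrame) -> np.ndarray:
    """0/1 matrix (marker x segregant): 1 where the superior allele is carried."""
    n = len(markers)
    G = np.empty((n, len(segregants)), dtype=np.int8)
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        rows = grp.index.to_numpy()
        for j, seg in enumerate(segregants):
            G[rows, j] = (seg.origin_at(chrom, pos) == SUPERIOR).astype(np.int8)
    return G


# ---------------------------------------------------------------------------
# meiosis and inbreeding


def _restrict(ends: np.ndarray, labels: np.ndarray, start: float, stop: float) -> tuple[list, list]:
    """Blocks of a source chromosome covering the half-open span (start, stop]."""
    out_e: list[float] = []
    out_l: list[int] = []
    i = int(np.searchsorted(ends, start, side="right"))
    while i < len(ends):
        e = min(float(ends[i]), stop)
        if e > start:
            out_e.append(e)
            out_l.append(int(labels[i]))
        if ends[i] >= stop:
            break
        i += 1
    return out_e, out_l


def _splice(
    a_ends: np.ndarray,
    a_labels: np.ndarray,
    b_ends: np.ndarray,
    b_labels: np.ndarray,
    cuts: np.ndarray,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamete chromosome reading source a, switching to b (and back) at cuts."""
    sources = ((a_ends, a_labels), (b_ends, b_labels))
    out_e: list[float] = []
    out_l: list[int] = []
    start = 0.0
    which = 0
    for stop in list(cuts) + [length]:
        e, l = _restrict(*sources[which], start, stop)
        out_e.extend(e)
        out_l.extend(l)
        which ^= 1
        start = stop
    return _merge_adjacent(np.array(out_e), np.array(out_l, dtype=np.int8))


def meiosis(
    mother: HaplotypeMosaic,
    father: HaplotypeMosaic,
    layout: GenomeLayout,
    seed_or_rng: "int | np.random.Generator",
) -> tuple[HaplotypeMosaic, HaplotypeMosaic, HaplotypeMosaic, HaplotypeMosaic]:
    """One meiosis of the diploid (mother, father): a four-spore tetrad.

    Spores 1/2 and 3/4 are the two complementary chromatid pairs.
    """
    if mother.layout != layout or father.layout != layout:
        raise ValueError("parent mosaics are not defined on the given layout")
    rng = as_rng(seed_or_rng, "meiosis")
    spores = [dict() for _ in range(4)]  # chrom -> (ends, labels)
    for chrom in layout.names:
        length = float(layout.length_of(chrom))
        n_co = rng.poisson(2.0 * layout.morgans(chrom))
        cuts = np.sort(rng.uniform(0.0, length, size=n_co))
        on_pair_b = rng.integers(0, 2, size=n_co).astype(bool)
        m = (mother.ends[chrom], mother.labels[chrom])
        f = (father.ends[chrom], father.labels[chrom])
        for pair, pair_cuts in enumerate((cuts[~on_pair_b], cuts[on_pair_b])):
            s1 = _splice(*m, *f, pair_cuts, length)
            s2 = _splice(*f, *m, pair_cuts, length)
            # independent assortment: orientation within the pair is random
            # per chromosome, so chromosomes segregate independently
            if rng.integers(2):
                s1, s2 = s2, s1
            spores[2 * pair][chrom] = s1
            spores[2 * pair + 1][chrom] = s2
    return tuple(
        HaplotypeMosaic(layout, {c: v[0] for c, v in s.items()}, {c: v[1] for c, v in s.items()})
        for s in spores
    )


def _sporulate_all(
    diploids: list[Diploid], layout: GenomeLayout, n_spores: int, rng: np.random.Generator
) -> list[HaplotypeMosaic]:
    """Sporulate every diploid equally often, subsample spores to the target.

    Every diploid contributes the same number of tetrads (ceil of demand),
    then ``n_spores`` spores are drawn without replacement; equal
    contribution plus uniform subsampling keeps drift per round minimal.
    """
    per = max(1, -(-n_spores // (4 * len(diploids))))  # ceil
    spores: list[HaplotypeMosaic] = []
    for d in diploids:
        for _ in range(per):
            spores.extend(meiosis(d[0], d[1], layout, rng))
    keep = rng.choice(len(spores), size=n_spores, replace=False)
    return [spores[i] for i in keep]


def inbreed(
    population: list[Diploid],
    rounds: int,
    layout: GenomeLayout,
    seed: int,
    n_spores: int | None = None,
    allow_selfing: bool = True,
) -> list[HaplotypeMosaic]:
    """Random-spore inbreeding: sporulate, pool spores, mass-mate, repeat.

    ``rounds`` counts post-F1 inbreeding generations: ``rounds=0`` returns
    spores of the initial cross (F1 segregants); ``rounds=6`` returns F7
    segregants.  Each round sporulates every diploid, pools the spores and
    forms new diploids by uniform random pairing (mating type abstracted).
    ``n_spores`` fixes the pool size per round (default four per diploid).
    With ``allow_selfing=False`` sister spores from one tetrad are kept
    apart when pairing (re-drawn if paired together).
    """
    if not population:
        raise ValueError("empty founding population")
    if rounds < 0:
        raise ValueError("rounds must be non-negative")
    rng_meio = substream(seed, "meiosis")
    rng_mate = substream(seed, "mating")
    diploids = list(population)
    target = n_spores if n_spores is not None else 4 * len(diploids)
    for _ in range(rounds):
        spores = _sporulate_all(diploids, layout, target, rng_meio)
        perm = rng_mate.permutation(len(spores))
        if not allow_selfing:
            perm = _avoid_sister_pairs(perm, rng_mate)
        diploids = [
            (spores[perm[2 * i]], spores[perm[2 * i + 1]]) for i in range(len(spores) // 2)
        ]
    return _sporulate_all(diploids, layout, target, rng_meio)


def random_spores(
    parents: Diploid, layout: GenomeLayout, n: int, seed: int
) -> list[HaplotypeMosaic]:
    """Random spore isolation: one uniformly chosen spore per independent
    meiosis, so segregant genotypes are independent Bernoulli(1/2) at every
    marker (unlike whole tetrads, which are exactly complementary)."""
    rng = as_rng(seed, "meiosis")
    out = []
    for _ in range(n):
        tetrad = meiosis(parents[0], parents[1], layout, rng)
        out.append(tetrad[rng.integers(4)])
    return out


def _avoid_sister_pairs(perm: np.ndarray, rng: np.random.Generator, tries: int = 100) -> np.ndarray:
    """Reshuffle until no pair joins two spores of the same tetrad (index//4)."""
    for _ in range(tries):
        pairs = perm[: len(perm) // 2 * 2].reshape(-1, 2)
        if not np.any(pairs[:, 0] // 4 == pairs[:, 1] // 4):
            break
        perm = rng.permutation(perm)
    return perm


# ---------------------------------------------------------------------------
# phenotype and selection


@dataclass(frozen=True)
class CausalLocus:
    chrom: str
    pos: int
    effect: float


@dataclass(frozen=True)
class PhenotypeSpec:
    """Polygenic architecture of the simulated trait.

    ``additive``: score = baseline + sum of effects over loci carrying the
    superior allele + Gaussian noise.  ``redundant``: loci listed in
    ``groups`` (tuples of indices into ``loci``) contribute the maximum over
    their members instead of the sum — two interchangeable causative genes
    give the same score whether one or both superior alleles are present.
    Loci outside every group stay additive.
    """

    loci: tuple[CausalLocus, ...]
    architecture: str = "additive"
    groups: tuple[tuple[int, ...], ...] = ()
    noise_sd: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.architecture not in ("additive", "redundant"):
            raise ValueError("architecture must be 'additive' or 'redundant'")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("redundant groups must be disjoint")
        if flat and (min(flat) < 0 or max(flat) >= len(self.loci)):
            raise ValueError("group indices out of range")


def _genetic_value(segregant: HaplotypeMosaic, spec: PhenotypeSpec) -> float:
    carries = np.array(
        [
            segregant.origin_at(l.chrom, np.array([l.pos]))[0] == SUPERIOR
            for l in spec.loci
        ],
        dtype=bool,
    )
    effects = np.array([l.effect for l in spec.loci])
    contrib = np.where(carries, effects, 0.0)
    if spec.architecture == "additive" or not spec.groups:
        return spec.baseline + contrib.sum()
    in_group = np.zeros(len(spec.loci), dtype=bool)
    total = 0.0
    for g in spec.groups:
        idx = np.array(g)
        in_group[idx] = True
        total += contrib[idx].max() if len(idx) else 0.0
    total += contrib[~in_group].sum()
    return spec.baseline + total


def assign_phenotype(
    segregant: HaplotypeMosaic, spec: PhenotypeSpec, seed_or_rng: "int | np.random.Generator"
) -> float:
    """Phenotype score of one segregant (genetic value + Gaussian noise)."""
    rng = as_rng(seed_or_rng, "phenotype")
    noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
    return _genetic_value(segregant, spec) + noise


def assign_phenotypes(
    population: list[HaplotypeMosaic], spec: PhenotypeSpec, seed: int
) -> np.ndarray:
    rng = substream(seed, "phenotype")
    return np.array([assign_phenotype(s, spec, rng) for s in population])


@dataclass
class Selection:
    """Top-k truncation selection result, ranked by descending phenotype."""

    segregants: list[HaplotypeMosaic]
    scores: np.ndarray
    indices: np.ndarray  # positions in the original population, rank order

    def __len__(self) -> int:
        return len(self.segregants)


def select_top(
    population: list[HaplotypeMosaic], phenotypes: np.ndarray, k: int
) -> Selection:
    """The k highest-phenotype segregants, ties broken by original order."""
    if k > len(population):
        raise ValueError(f"k={k} exceeds population size {len(population)}")
    order = np.argsort(-np.asarray(phenotypes, dtype=float), kind="stable")[:k]
    return Selection(
        segregants=[population[i] for i in order],
        scores=np.asarray(phenotypes, dtype=float)[order],
        indices=order,
    )


def select_random(
    population: list[HaplotypeMosaic], phenotypes: np.ndarray, k: int, seed: int
) -> Selection:
    """An unselected control pool: k segregants drawn uniformly at random."""
    if k > len(population):
        raise ValueError(f"k={k} exceeds population size {len(population)}")
    rng = substream(seed, "selection")
    idx = rng.choice(len(population), size=k, replace=False)
    scores = np.asarray(phenotypes, dtype=float)[idx]
    order = np.argsort(-scores, kind="stable")
    idx = idx[order]
    return Selection([population[i] for i in idx], scores[order], idx)


# ---------------------------------------------------------------------------
# sequencing


@dataclass(frozen=True)
class SequencingSpec:
    """Depth and error model for pooled or per-segregant short reads.

    Depth per marker is negative-binomial around ``mean_depth`` with shape
    ``dispersion`` (variance m + m^2/k; ``inf`` gives Poisson); each read's
    allele call flips with ``error_rate``; reported mean base quality is
    Gaussian around ``mean_phred`` truncated to [2, 41].
    """

    mean_depth: float = 50.0
    dispersion: float = 10.0
    error_rate: float = 0.002
    mean_phred: float = 38.0
    phred_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")


def _draw_depth(spec: SequencingSpec, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    if spec.mean_depth == 0:
        return np.zeros(shape, dtype=np.int64)
    if np.isinf(spec.dispersion):
        return rng.poisson(spec.mean_depth, size=shape)
    k = spec.dispersion
    p = k / (k + spec.mean_depth)
    return rng.negative_binomial(k, p, size=shape)


def _draw_qual(spec: SequencingSpec, depth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(spec.mean_phred, spec.phred_sd, size=depth.shape)
    q = np.clip(q, 2.0, 41.0)
    return np.where(depth > 0, q, 0.0)


def sequence_pool(
    selection: Selection,
    markers: pd.DataFrame,
    spec: SequencingSpec,
    seed: int,
    sample: str = "pool",
) -> AlleleCountMatrix:
    """Pooled sequencing of a selection: equal cell numbers per segregant.

    Each read at a marker comes from a uniformly chosen segregant's true
    allele, flipped with the per-base error rate; equivalently the superior
    count is binomial with success probability q(1-e) + (1-q)e where q is
    the superior-allele fraction among pooled segregants.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    rng = as_rng(seed, "sequencing")
    G = genotype_matrix(selection.segregants, markers)
    q = G.mean(axis=1)
    p_obs = q * (1 - spec.error_rate) + (1 - q) * spec.error_rate
    depth = _draw_depth(spec, (len(markers),), rng)
    sup = rng.binomial(depth, p_obs)
    inf = depth - sup
    qual = _draw_qual(spec, depth, rng)
    shape = (len(markers), 1)
    return AlleleCountMatrix(
        markers=markers.reset_index(drop=True),
        samples=[sample],
        sup=sup.reshape(shape),
        inf=inf.reshape(shape),
        qual=qual.reshape(shape),
        mask=np.zeros(shape, dtype=bool),
    )


def sequence_segregants(
    selection: Selection,
    markers: pd.DataFrame,
    spec: SequencingSpec,
    seed: int,
    prefix: str = "seg",
) -> AlleleCountMatrix:
    """Individual sequencing: one count column per selected segregant."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    rng = as_rng(seed, "sequencing")
    G = genotype_matrix(selection.segregants, markers)
    p_obs = np.where(G == 1, 1 - spec.error_rate, spec.error_rate)
    depth = _draw_depth(spec, G.shape, rng)
    sup = rng.binomial(depth, p_obs)
    inf = depth - sup
    qual = _draw_qual(spec, depth, rng)
    names = [f"{prefix}{i + 1:02d}" for i in range(len(selection))]
    return AlleleCountMatrix(
        markers=markers.reset_index(drop=True),
        samples=names,
        sup=sup,
        inf=inf,
        qual=qual,
        mask=np.zeros(G.shape, dtype=bool),
    )


def sequence_parents(
    layout: GenomeLayout, markers: pd.DataFrame, spec: SequencingSpec, seed: int
) -> AlleleCountMatrix:
    """Sequence both parental haploids (samples 'superior' and 'inferior')."""
    sup_parent = HaplotypeMosaic.uniform(layout, SUPERIOR)
    inf_parent = HaplotypeMosaic.uniform(layout, INFERIOR)
    sel = Selection([sup_parent, inf_parent], np.array([0.0, 0.0]), np.array([0, 1]))
    acm = sequence_segregants(sel, markers, spec, seed, prefix="parent")
    acm.samples = ["superior", "inferior"]
    return acm
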