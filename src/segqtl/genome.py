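"""Genome layout and recombinant-haplotype (mosaic) containers.

A segregant genome is represented as a :class:`HaplotypeMosaic`: per
chromosome, an alternating run of blocks inherited from the superior or the
inferior parent.  Blocks are stored as sorted block-end coordinates plus a
parent label per block, which makes parent-of-origin lookup at arbitrary
marker positions a single ``searchsorted``.

Coordinates are 1-based inclusive base pairs throughout, matching how QTL
boundaries are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUPERIOR = 0
INFERIOR = 1

_LABELS = {SUPERIOR: "superior", INFERIOR: "inferior"}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, physical lengths (bp) and genetic-map density.

    ``cm_per_kb`` converts physical to genetic distance; 0.35 cM/kb is a
    typical genome-wide average for *S. cerevisiae*.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    cm_per_kb: float = 0.35

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.cm_per_kb < 0:
            raise ValueError("map density must be non-negative")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return self.length_of(chrom) / 1000.0 * self.cm_per_kb / 100.0


@dataclass
class HaplotypeMosaic:
    """One haploid genome as parental blocks per chromosome.

    ``ends[c]`` holds strictly increasing block-end coordinates, the last
    equal to the chromosome length; ``labels[c]`` holds the parent of origin
    of each block (``SUPERIOR``/``INFERIOR``).  Adjacent blocks always carry
    different labels (normalised on construction).
    """

    layout: GenomeLayout
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def uniform(cls, layout: GenomeLayout, label: int) -> "HaplotypeMosaic":
        """A non-recombinant genome inherited wholly from one parent."""
        ends = {c: np.array([float(l)]) for c, l in zip(layout.names, layout.lengths)}
        labels = {c: np.array([label], dtype=np.int8) for c in layout.names}
        return cls(layout, ends, labels)

    @classmethod
    def from_blocks(
        cls, layout: GenomeLayout, blocks: dict[str, list[tuple[float, int]]]
    ) -> "HaplotypeMosaic":
        """Build from per-chromosome ``[(block_end, label), ...]`` lists."""
        ends: dict[str, np.ndarray] = {}
        labels: dict[str, np.ndarray] = {}
        for chrom in layout.names:
            spec = blocks[chrom]
            e = np.array([b[0] for b in spec], dtype=float)
            l = np.array([b[1] for b in spec], dtype=np.int8)
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"block ends not increasing on {chrom}")
            if e[-1] != layout.length_of(chrom):
                raise ValueError(f"last block must end at chromosome length on {chrom}")
            e, l = _merge_adjacent(e, l)
            ends[chrom], labels[chrom] = e, l
        return cls(layout, ends, labels)

    def origin_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Parent label at each (1-based) position on a chromosome."""
        idx = np.searchsorted(self.ends[chrom], np.asarray(positions, dtype=float), side="left")
        return self.labels[chrom][idx]

    def n_blocks(self) -> int:
        return int(sum(len(l) for l in self.labels.values()))

    def block_lengths(self, chrom: str) -> np.ndarray:
        e = self.ends[chrom]
        return np.diff(np.concatenate([[0.0], e]))

    def mean_block_length(self) -> float:
        lens = np.concatenate([self.block_lengths(c) for c in self.layout.names])
        return float(lens.mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMosaic):
            return NotImplemented
        if self.layout != other.layout:
            return False
        return all(
            np.array_equal(self.ends[c], other.ends[c])
            and np.array_equal(self.labels[c], other.labels[c])
            for c in self.layout.names
        )


def _merge_adjacent(ends: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length blocks and merge runs of equal labels."""
    keep_e: list[float] = []
    keep_l: list[int] = []
    prev = 0.0
    for e, l in zip(ends, labels):
        if e <= prev:
            continue
        if keep_l and keep_l[-1] == l:
            keep_e[-1] = e
        else:
            keep_e.append(e)
            keep_l.append(int(l))
        prev = e
    return np.array(keep_e, dtype=float), np.array(keep_l, dtype=np.int8)


def label_name(label: int) -> str:
    return _LABELS[int(label)]
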