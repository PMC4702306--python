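"""QTL intervals: the called linkage regions, and arithmetic on them.

Coordinates are 1-based inclusive, matching how QTL boundaries are reported
in the yeast literature; BED export (0-based half-open) lives in ``ioutils``.
Interval width follows the reporting convention width = end - start, so a
region spanning 247,466-277,019 bp is 29,553 bp wide (~30 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class QTLInterval:
    """A called linkage region.

    ``direction`` is "superior" when the region is linked to the superior
    parent's genome (pooled variant frequency above 0.5, or positive
    parent-of-origin average), "inferior" otherwise.  ``tier`` records the
    evidence source: "pooled", "individual" or "both".
    """

    chrom: str
    start: int
    end: int
    peak: int
    direction: str
    tier: str = "pooled"
    peak_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start exceeds end")
        if self.direction not in ("superior", "inferior"):
            raise ValueError("direction must be 'superior' or 'inferior'")

    @property
    def width(self) -> int:
        return interval_width(self)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def interval_width(interval: QTLInterval) -> int:
    """Width in bp under the reporting convention end - start."""
    return interval.end - interval.start


def compare_intervals(a: QTLInterval, b: QTLInterval) -> int:
    """Width difference a - b in bp (positive when a is wider)."""
    return interval_width(a) - interval_width(b)


def round_to_kb(bp: int) -> int:
    """Nearest-kb rounding for reporting (113,147 bp -> 113 kb)."""
    return int(round(bp / 1000.0))


def round_to_10kb(bp: int) -> int:
    """Nearest-10-kb rounding for reporting (29,553 bp -> 30 kb)."""
    return 10 * int(round(bp / 10000.0))


def central_subinterval(interval: QTLInterval, fraction: float = 0.5) -> QTLInterval:
    """The central ``fraction`` of an interval (gene-listing convention)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    mid = (interval.start + interval.end) / 2.0
    half = (interval.end - interval.start) * fraction / 2.0
    return replace(interval, start=int(round(mid - half)), end=int(round(mid + half)))


def subtract_unselected(
    selected: list[QTLInterval], unselected: list[QTLInterval]
) -> list[QTLInterval]:
    """Remove portions of selected intervals covered by same-direction
    unselected intervals (the control-pool correction); empty remnants drop.

    The peak is kept when it survives; otherwise it moves to the remnant
    midpoint.
    """
    out: list[QTLInterval] = []
    for sel in selected:
        spans = [(sel.start, sel.end)]
        for uns in unselected:
            if uns.chrom != sel.chrom or uns.direction != sel.direction:
                continue
            spans = _cut(spans, uns.start, uns.end)
        for s, e in spans:
            peak = sel.peak if s <= sel.peak <= e else (s + e) // 2
            out.append(replace(sel, start=s, end=e, peak=peak))
    return out


def _cut(spans: list[tuple[int, int]], start: int, end: int) -> list[tuple[int, int]]:
    """Remove [start, end] (1-based inclusive) from each span."""
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if end < s or start > e:
            out.append((s, e))
            continue
        if s < start:
            out.append((s, start - 1))
        if e > end:
            out.append((end + 1, e))
    return out
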