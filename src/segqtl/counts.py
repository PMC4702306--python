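"""Allele-count containers shared by the simulator and both mapping engines."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class AlleleCountMatrix:
    """Read counts for the superior/inferior allele, per marker x sample.

    ``markers`` is a genome-sorted frame with at least ``chrom`` and ``pos``
    columns; array shapes are ``(n_markers, n_samples)``.  ``mask`` flags
    marker/sample cells excluded by quality filtering (True = masked out);
    sequencing emits an all-False mask.
    """

    markers: pd.DataFrame
    samples: list[str]
    sup: np.ndarray
    inf: np.ndarray
    qual: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n, s = len(self.markers), len(self.samples)
        for name in ("sup", "inf", "qual", "mask"):
            arr = getattr(self, name)
            if arr.shape != (n, s):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, s)}")
        if len(set(self.samples)) != s:
            raise ValueError("sample labels must be unique")
        if (self.sup < 0).any() or (self.inf < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def coverage(self) -> np.ndarray:
        return self.sup + self.inf

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(sup, inf, qual, mask) arrays for one sample."""
        j = self.sample_index(sample)
        return self.sup[:, j], self.inf[:, j], self.qual[:, j], self.mask[:, j]

    def with_mask(self, mask: np.ndarray) -> "AlleleCountMatrix":
        return replace(self, mask=mask)

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame (chrom, pos, sample, superior_count, inferior_count, mean_phred)."""
        frames = []
        for j, s in enumerate(self.samples):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": self.markers["chrom"].to_numpy(),
                        "pos": self.markers["pos"].to_numpy(),
                        "sample": s,
                        "superior_count": self.sup[:, j],
                        "inferior_count": self.inf[:, j],
                        "mean_phred": self.qual[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)
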