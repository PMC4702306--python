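"""Run configuration: one YAML-serialisable object covering the simulator,
both mapping engines and the reporting thresholds.

Defaults mirror the study design the simulator emulates: 288 F1 segregants
screened and the top 27 pooled; six rounds of inbreeding to 768 F7
segregants; coverage/quality cutoffs 15 and 35; FDR 0.007; 3-kb windows;
+/-0.7 averaging threshold.  The genome defaults to a three-chromosome
scale-down of the ~12 Mb, ~23,150-marker yeast cross (same marker density).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .genome import GenomeLayout
from .simulate import CausalLocus, PhenotypeSpec, SequencingSpec

DEFAULT_CHROM_LENGTH = 750_000
DEFAULT_N_CHROMS = 3
# genome-wide marker count scaled by genome fraction: 23150 * (3*0.75 Mb / 12 Mb)
DEFAULT_N_MARKERS = 4340


@dataclass
class RunConfig:
    chrom_names: tuple[str, ...] = tuple(f"chr{r}" for r in ("I", "II", "III"))
    chrom_lengths: tuple[int, ...] = (DEFAULT_CHROM_LENGTH,) * DEFAULT_N_CHROMS
    cm_per_kb: float = 0.35
    n_markers: int = DEFAULT_N_MARKERS
    n_f1: int = 288
    n_f7: int = 768
    rounds: int = 6
    k_selected: int = 27
    phenotype: PhenotypeSpec = field(
        default_factory=lambda: PhenotypeSpec(
            loci=(CausalLocus("chrII", 375_000, 1.0),), noise_sd=0.25
        )
    )
    sequencing: SequencingSpec = field(default_factory=SequencingSpec)
    min_coverage: int = 15
    min_quality: float = 35.0
    bandwidth: float = 20_000.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    fdr_q: float = 0.007
    sigma: float = 1000.0
    window: int = 3000
    avg_threshold: float = 0.7
    seed: int = 0

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            names=tuple(self.chrom_names),
            lengths=tuple(self.chrom_lengths),
            cm_per_kb=self.cm_per_kb,
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phenotype"]["loci"] = [list(asdict(l).values()) for l in self.phenotype.loci]
        d["phenotype"]["groups"] = [list(g) for g in self.phenotype.groups]
        d["chrom_names"] = list(self.chrom_names)
        d["chrom_lengths"] = list(self.chrom_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phenotype", {}))
        if ph:
            ph["loci"] = tuple(CausalLocus(c, int(p), float(e)) for c, p, e in ph.get("loci", []))
            ph["groups"] = tuple(tuple(g) for g in ph.get("groups", []))
            d["phenotype"] = PhenotypeSpec(**ph)
        sq = d.pop("sequencing", None)
        if sq:
            d["sequencing"] = SequencingSpec(**sq)
        d["chrom_names"] = tuple(d.get("chrom_names", cls.chrom_names))
        d["chrom_lengths"] = tuple(int(x) for x in d.get("chrom_lengths", cls.chrom_lengths))
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Short digest of the canonical YAML form, embedded in outputs."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}
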