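"""Pooled-segregant (bulk segregant) QTL mapping.

Simulates the selected and unselected 27-segregant pools, maps linkage
from the pooled variant frequencies, removes control-pool linkage, and
prints the called interval with its width and gene-scale coordinates.
"""

from segqtl import (
    CausalLocus,
    PhenotypeSpec,
    RunConfig,
    map_experiment_pooled,
    round_to_kb,
    simulate_experiment,
)

cfg = RunConfig(
    seed=1,
    phenotype=PhenotypeSpec(loci=(CausalLocus("chrII", 375_000, 1.0),), noise_sd=0.0),
)
exp = simulate_experiment(cfg, generation="f1")
curve, intervals = map_experiment_pooled(exp)

print("called QTL intervals (after subtracting unselected-pool linkage):")
for iv in intervals:
    print(
        f"  {iv.chrom}:{iv.start:,}-{iv.end:,}  direction={iv.direction}"
        f"  peak={iv.peak:,} (fitted frequency {iv.peak_value:.2f})"
        f"  width ~{round_to_kb(iv.width)} kb"
    )
hit = any(iv.contains("chrII", 375_000) for iv in intervals)
print(f"causal locus chrII:375,000 covered by a call: {hit}")
# The interval's fitted frequency far above 0.5 marks preferential
# inheritance from the superior parent among the selected segregants.
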