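"""Simulate a yeast cross with selection and sequencing.

Builds the default in-silico design — two haploid parents differing at
~4,340 SNPs over a three-chromosome genome, 288 F1 segregants screened for
a single-locus trait, the top 27 retained — and prints what the simulated
sequencing produced.
"""

import numpy as np

from segqtl import CausalLocus, PhenotypeSpec, RunConfig, simulate_experiment

cfg = RunConfig(
    seed=1,
    phenotype=PhenotypeSpec(loci=(CausalLocus("chrII", 375_000, 1.0),), noise_sd=0.25),
)
exp = simulate_experiment(cfg, generation="f1")

print(f"markers: {len(exp.markers)} SNPs over {len(exp.layout.names)} chromosomes")
print(f"population: {len(exp.population)} F1 segregants, top {len(exp.selected)} selected")
print(f"selected phenotype range: {exp.selected.scores.min():.2f}..{exp.selected.scores.max():.2f}")
cov = exp.selected_pool.coverage()[:, 0]
print(f"pooled coverage: mean {cov.mean():.1f} reads/marker")
f = exp.selected_pool.sup[:, 0] / np.maximum(cov, 1)
on = (exp.markers["chrom"] == "chrII").to_numpy()
print(f"pool superior-allele frequency: genome median {np.median(f):.2f}, "
      f"chrII median {np.median(f[on]):.2f}")
# A genome-wide median near 0.5 is Mendelian segregation; the elevated
# chrII median is the footprint of selection at the causal locus.
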