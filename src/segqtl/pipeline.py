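"""End-to-end convenience layer: simulate an experiment, map it both ways.

The simulated design mirrors the pooled-segregant protocol: cross two
haploid parents, screen a segregant population for the phenotype, keep the
top k (default 27) plus an equal-size unselected control pool, sequence the
parents, both pools, and the selected segregants individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .config import RunConfig
from .counts import AlleleCountMatrix
from .genome import INFERIOR, SUPERIOR, GenomeLayout, HaplotypeMosaic
from .simulate import (
    Selection,
    assign_phenotypes,
    inbreed,
    make_parental_markers,
    select_random,
    select_top,
    sequence_parents,
    sequence_pool,
    sequence_segregants,
)


@dataclass
class SimulatedExperiment:
    config: RunConfig
    layout: GenomeLayout
    markers: pd.DataFrame
    population: list[HaplotypeMosaic]
    phenotypes: np.ndarray
    selected: Selection
    unselected: Selection
    selected_pool: AlleleCountMatrix
    unselected_pool: AlleleCountMatrix
    individual: AlleleCountMatrix
    parents: AlleleCountMatrix


def simulate_experiment(config: RunConfig, generation: str = "f1") -> SimulatedExperiment:
    """Run the whole in-silico protocol for an F1 or F7 population.

    ``generation='f1'`` sporulates the hybrid once (``n_f1`` spores, no
    inbreeding); ``'f7'`` applies ``rounds`` rounds of random-spore mass
    mating first (``n_f7`` spores per round).
    """
    if generation not in ("f1", "f7"):
        raise ValueError("generation must be 'f1' or 'f7'")
    layout = config.layout()
    markers = make_parental_markers(layout, config.n_markers, config.seed)
    sup = HaplotypeMosaic.uniform(layout, SUPERIOR)
    inf = HaplotypeMosaic.uniform(layout, INFERIOR)
    rounds = 0 if generation == "f1" else config.rounds
    n_spores = config.n_f1 if generation == "f1" else config.n_f7
    population = inbreed([(sup, inf)], rounds, layout, config.seed, n_spores=n_spores)
    phenotypes = assign_phenotypes(population, config.phenotype, config.seed)
    selected = select_top(population, phenotypes, config.k_selected)
    unselected = select_random(population, phenotypes, config.k_selected, config.seed)
    rng_seq = substream(config.seed, "sequencing")
    parents = sequence_parents(layout, markers, config.sequencing, config.seed)
    selected_pool = sequence_pool(
        selected, markers, config.sequencing, rng_seq, sample="selected_pool"
    )
    unselected_pool = sequence_pool(
        unselected, markers, config.sequencing, rng_seq, sample="unselected_pool"
    )
    individual = sequence_segregants(selected, markers, config.sequencing, rng_seq)
    return SimulatedExperiment(
        config=config,
        layout=layout,
        markers=markers,
        population=population,
        phenotypes=phenotypes,
        selected=selected,
        unselected=unselected,
        selected_pool=selected_pool,
        unselected_pool=unselected_pool,
        individual=individual,
        parents=parents,
    )


def map_experiment_pooled(exp: SimulatedExperiment, subtract_control: bool = True):
    """Pooled mapping of the selected pool, minus control-pool linkage."""
    from . import pooled

    cfg = exp.config
    _, curve, sel_iv = pooled.map_pool(
        exp.selected_pool,
        "selected_pool",
        min_coverage=cfg.min_coverage,
        min_quality=cfg.min_quality,
        bandwidth=cfg.bandwidth,
        alpha=cfg.alpha,
        n_pool=len(exp.selected),
    )
    if not subtract_control:
        return curve, sel_iv
    _, _, uns_iv = pooled.map_pool(
        exp.unselected_pool,
        "unselected_pool",
        min_coverage=cfg.min_coverage,
        min_quality=cfg.min_quality,
        bandwidth=cfg.bandwidth,
        alpha=cfg.alpha,
        n_pool=len(exp.unselected),
    )
    return curve, pooled.subtract_unselected(sel_iv, uns_iv)


def map_experiment_individual(exp: SimulatedExperiment, k: int | None = None):
    """Individual mapping of the selected segregants, phenotype ordered."""
    from . import individual as indiv
    from . import pooled

    cfg = exp.config
    counts = pooled.quality_filter(exp.individual, cfg.min_coverage, cfg.min_quality)
    # selection is already ranked by descending phenotype
    ranking = np.arange(len(counts.samples))
    return indiv.map_individuals(
        counts,
        exp.parents,
        exp.layout,
        ranking=ranking,
        k=k,
        pseudocount=cfg.pseudocount,
        error_rate=cfg.sequencing.error_rate,
        fdr_q=cfg.fdr_q,
        sigma=cfg.sigma,
        window=cfg.window,
        threshold=cfg.avg_threshold,
    )
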