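# Methods

This note documents the models behind `segqtl`, the defaults and why they
were chosen, and what the synthetic data generator does and does not
emulate.

## Cross and inbreeding model

**Meiosis.** Each chromosome recombines as a four-chromatid bivalent: the
crossover count is Poisson with mean twice the chromosome's genetic length
in Morgans (genetic length = physical length × map density), crossover
positions are uniform, and there is no crossover interference. Each
crossover is resolved on one of the two chromatid pairs with equal
probability, so a tetrad is two complementary spore pairs carrying exactly
two copies of each parental allele at every locus, and the expected
crossover count per spore equals the map length in Morgans. Orientation
within each pair is randomised per chromosome, giving independent
assortment. The default map density, 0.35 cM/kb, is a typical
genome-average for *S. cerevisiae*; the Poisson/uniform/no-interference
choice is the standard neutral model when the cross's true map is unknown,
and both are configurable.

**Inbreeding.** A round of inbreeding sporulates every diploid, pools the
spores and mass-mates them by uniform random pairing; mating type is
abstracted away (the laboratory protocol randomises mating, and modelling
MAT would halve the admissible pairings without changing the statistics of
the resulting genomes). An optional flag keeps sister spores of one tetrad
from self-pairing. `rounds=0` returns the spores of the founding cross
(F1); `rounds=6` returns F7 segregants. Because the operation's interface
does not otherwise fix population sizes, a `n_spores` parameter sets the
spore pool per round (default four per diploid); every diploid contributes
equally many tetrads and the pool is then subsampled uniformly, which
keeps genetic drift per round near its minimum for the chosen pool size.
The defaults used in the end-to-end pipeline are 288 F1 spores from the
single hybrid and 768 spores per round for the F7 design, with the top 27
segregants selected in either case.

A separate `random_spores` helper models random spore isolation — one
uniformly chosen spore per independent meiosis — which is the right input
for calibration studies, because whole tetrads are exactly complementary
and therefore carry no segregation noise at all.

**Phenotype.** Additive architecture: score = baseline + Σ effect ×
[superior allele at locus] + Gaussian noise. Redundant-groups
architecture: loci in a group contribute the maximum over members, so two
interchangeable causative genes yield the same score whether a segregant
carries one or both superior alleles — the mechanism by which a polygenic
trait can be supported by partially different gene sets in different
selections. Truncation selection keeps the k highest scores with ties
broken by original order (documented because pool membership propagates
into every downstream map).

**Sequencing.** Depth per marker is negative-binomial around the mean
(default 50×, shape 10; infinite shape gives Poisson), each read's allele
flips with the per-base error rate (default 0.002), and the reported mean
base quality is Gaussian around PHRED 38 truncated to [2, 41]. Pooled
reads draw their source segregant uniformly, which makes the superior
count at a marker exactly binomial with success probability
q(1−e) + (1−q)e for pool fraction q. No read-level artefacts beyond this
(no FASTQ, alignment or mapping bias) are modelled.

**Scale.** The default genome is a three-chromosome scale-down (3 ×
750 kb) of a ~12 Mb, 16-chromosome genome, with the marker count scaled by
genome fraction (4,340 of ~23,150) so the marker density (~520 bp spacing)
matches the full-scale design. All simulation-backed results in the test
suite and acceptance script use this scale; it keeps a full
simulate-plus-both-engines replicate under a second while preserving the
per-chromosome statistics (marker density, map length per Mb, pool sizes)
that the analyses actually consume.

## Pooled mapping

Variant frequencies are computed per marker after masking cells with
coverage < 15 or mean PHRED < 35 (inclusive thresholds). The published
analyses this engine mirrors used a smoothing-spline generalized linear
mixed model for the frequency trend; `segqtl` instead uses a
kernel-weighted local binomial estimator — Gaussian kernel weights
(default bandwidth 20 kb) applied to read counts, fitted frequency =
weighted success fraction with a half-read continuity correction,
confidence band by normal approximation on the logit scale — which
reproduces the role of that smoother (trend plus band against 0.5) with a
single transparent bandwidth parameter.

The band's effective trial count matters: pooled reads are a two-stage
sample (segregant composition of the pool, then reads), and the
composition stage is shared by all markers in a linkage block, so
smoothing cannot average it away. The band therefore caps the effective
trials as 1/n_eff = 1/n_reads_eff + 1/n_pool (Kish effective reads from
the kernel weights; n_pool = 27 by default). Without this cap the
composition noise of a 27-segregant pool (sd ≈ 0.10 in the true pool
frequency) produces wide spurious deviations that read noise alone cannot
explain.

Intervals are maximal runs of covered markers whose band excludes 0.5,
boundaries anchored at the first/last marker of the run, peak at the most
extreme fitted value, direction by the side of 0.5. Coordinates are
1-based inclusive internally; BED exports are 0-based half-open. Linkage
present in an unselected control pool (same direction, same chromosome)
is subtracted by interval arithmetic to remove loci enriched by the
breeding protocol rather than the trait. The exact binomial linkage test
uses per-segregant trials (successes = segregants carrying the superior
allele) and the standard two-sided construction summing all outcomes no
more probable than the observed one; no multiple-testing correction is
applied by default (raw p against 0.05, matching how such per-SNP scores
are conventionally reported), with Benjamini–Hochberg available in the
individual engine.

## Individual mapping

Read counts become genotype distributions p(allele) = (count + α)/(total
+ 2α) with pseudocount α = 1; the pseudocount is required because
parental profiles are near-degenerate and raw KL divergence would be
infinite. The parent of origin at a SNP is the parent with the smaller
divergence; the signed score D_inferior − D_superior is positive for
superior-parent inheritance. Equal divergences are undetermined.

The assignment p-value fed to the FDR filter is the upper-tail exact
binomial probability of the assigned-allele count under the non-assigned
parent's error model (the assigned allele arises only through sequencing
error, at the configured error rate). A tail probability, rather than the
bare point probability, keeps the p-value monotone in the strength of
evidence. Benjamini–Hochberg runs within each segregant separately
(conservative q = 0.007, i.e. a cut-off chosen to be safe when correcting
many samples separately), step-up inclusive at the threshold; failing
assignments become undetermined and their scores are zeroed.

Scores are smoothed along each chromosome with a Gaussian kernel in
genomic coordinates (Nadaraya–Watson, row-normalised): a constant series
passes through unchanged and an interior impulse on a regular grid
conserves its mass. Sigma defaults to 1000 bp; the acceptance-level
results are insensitive across 500–2000 bp. Windows are non-overlapping
3-kb tiles anchored at position 1 (a tiling stride matches the ternary
per-locus output; the stride is configurable). A window's summed score
strictly above 0 calls +1, strictly below 0 calls −1, empty or zero-sum
windows call 0; a minimum-evidence threshold τ is available. Ternary
tracks of the k top-ranked segregants are arithmetically averaged and
maximal runs of windows strictly beyond ±0.7 (ties excluded) become
intervals. The "distance-based method followed by segmentation" is
exactly this smooth-then-window pipeline; no separate change-point
algorithm is used.

## Calibration and degenerate inputs

- Markers with zero post-filter coverage are excluded from smoothing, not
  imputed; zero-coverage genotype distributions are uniform and carry no
  assignment.
- Single-marker chromosomes yield a curve equal to that marker's
  (continuity-corrected) frequency with its binomial band.
- The exact binomial test is discrete: with 27 segregants the largest
  achievable two-sided size below 0.05 is ≈0.019, so null calibration is
  demonstrated with 396 independent segregants (random spore isolation),
  where the achievable size is within 0.1% of the nominal 5% — the count
  was chosen from the binomial pmf, not fitted to simulation output.
  Calibration uses one marker per independently assorting chromosome so
  the per-marker tests are mutually independent; linked markers share
  segregation noise and would make the observed rejection fraction
  over-dispersed around its expectation.
- Allele-frequency conservation in unselected populations is asserted on
  the genome median and on ≥95% of markers (a handful of 3-SE excursions
  is expected by chance, and linked markers drift together).

## What passing tests do and do not show

The generator reproduces the statistical structure the analyses assume —
Mendelian segregation, linkage blocks shrinking under inbreeding,
selection-driven allele-frequency shifts, binomial read sampling with
errors — but not alignment artefacts, coverage bias along the genome,
segmental aneuploidy, gene-conversion tracts, or crossover interference.
Recovery rates measured here therefore bound performance under ideal
mapping conditions; real data adds noise sources the quality filters are
designed to absorb but that are not themselves simulated.

## Protein utilities

Candidate-regulator comparisons use global pairwise alignment
(BLOSUM62, gap open −10, extend −0.5; "similar" = positive substitution
score), reporting percent identity and similarity over aligned columns
with the scoring scheme recorded in the output. The bundled
`cup2_haa1_synthetic.fasta` contains synthetic stand-in peptides (225 and
694 residues) for the two paralogous regulators, generated to have a
Cup2-length N-terminal region of elevated similarity; they exercise the
code paths but are not the real protein sequences.

## Known limitations

- The crossover model has no interference; interval widths in simulation
  may differ modestly from a cross with strong interference.
- Mass mating ignores mating type and sporulation-efficiency biology; the
  optional viability weighting (inadvertent selection) is off by default.
- The pooled confidence band is a plug-in normal approximation on the
  logit scale; for very sparse coverage exact intervals would be wider.
- The FDR filter corrects within each segregant; it does not model
  correlation between neighbouring SNPs (the Gaussian smoothing stage is
  what absorbs residual isolated errors).
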