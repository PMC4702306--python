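"""Simulator: markers, meiosis, inbreeding, phenotype, selection, sequencing."""

import numpy as np
import pytest

from segqtl._rng import substream
from segqtl.genome import GenomeLayout, HaplotypeMosaic, INFERIOR, SUPERIOR
from segqtl.simulate import (
    CausalLocus,
    PhenotypeSpec,
    Selection,
    SequencingSpec,
    assign_phenotype,
    assign_phenotypes,
    genotype_matrix,
    inbreed,
    make_parental_markers,
    meiosis,
    select_top,
    sequence_pool,
    sequence_segregants,
)


# ---------------------------------------------------------------------------
# parental markers


class TestMakeParentalMarkers:
    def test_paper_scale_spacing(self):
        """23,150 markers on a 12 Mbp genome -> mean spacing ~518 bp."""
        layout = GenomeLayout(
            names=tuple(f"c{i}" for i in range(16)), lengths=(750_000,) * 16
        )
        m = make_parental_markers(layout, 23_150, seed=0)
        assert len(m) == 23_150
        spacing = layout.total_length / len(m)
        assert spacing == pytest.approx(518, rel=0.01)

    def test_empty(self, small_layout):
        assert len(make_parental_markers(small_layout, 0, seed=0)) == 0

    def test_sorted_unique_biallelic(self, small_layout):
        m = make_parental_markers(small_layout, 500, seed=3)
        for _, grp in m.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].is_unique
        assert (m["superior_allele"] != m["inferior_allele"]).all()

    def test_seeded_draw_matches_uniform_oracle(self):
        """Positions equal an independent seeded uniform draw without replacement."""
        layout = GenomeLayout(names=("c1",), lengths=(10_000,))
        m = make_parental_markers(layout, 10, seed=42)
        oracle = substream(42, "markers")
        oracle.multinomial(10, [1.0])  # same stream consumption order
        expect = np.sort(oracle.choice(10_000, size=10, replace=False) + 1)
        assert np.array_equal(m["pos"].to_numpy(), expect)

    def test_impossible_density_errors(self):
        layout = GenomeLayout(names=("c1",), lengths=(10,))
        with pytest.raises(ValueError):
            make_parental_markers(layout, 11, seed=0)


# ---------------------------------------------------------------------------
# meiosis


class TestMeiosis:
    def test_homozygous_diploid_gives_identical_spores(self, small_layout, rng):
        parent = HaplotypeMosaic.uniform(small_layout, SUPERIOR)
        spores = meiosis(parent, parent, small_layout, rng)
        pos = np.arange(1, 300_000, 997)
        for s in spores:
            assert np.all(s.origin_at("chrA", pos) == SUPERIOR)

    def test_zero_map_density_gives_no_recombination(self, rng):
        layout = GenomeLayout(names=("c1",), lengths=(100_000,), cm_per_kb=0.0)
        mother = HaplotypeMosaic.uniform(layout, SUPERIOR)
        father = HaplotypeMosaic.uniform(layout, INFERIOR)
        spores = meiosis(mother, father, layout, rng)
        labels = sorted(int(s.labels["c1"][0]) for s in spores)
        assert all(s.n_blocks() == 1 for s in spores)
        assert labels == [SUPERIOR, SUPERIOR, INFERIOR, INFERIOR]

    def test_crossover_rate_matches_poisson_expectation(self, rng):
        """Mean crossovers per spore chromosome ~ genetic length in Morgans."""
        layout = GenomeLayout(names=("c1",), lengths=(1_000_000,), cm_per_kb=0.03)
        expect = layout.morgans("c1")  # 0.3 Morgans
        mother = HaplotypeMosaic.uniform(layout, SUPERIOR)
        father = HaplotypeMosaic.uniform(layout, INFERIOR)
        n_rep = 1000
        counts = []
        for _ in range(n_rep):
            for s in meiosis(mother, father, layout, rng):
                counts.append(s.n_blocks() - 1)
        mean = np.mean(counts)
        se = np.sqrt(expect / len(counts))
        assert abs(mean - expect) < 3 * se

    def test_tetrad_complementarity(self, small_layout, parents, rng):
        """Every tetrad carries exactly two superior alleles at every locus."""
        markers = make_parental_markers(small_layout, 200, seed=5)
        for _ in range(10):
            spores = meiosis(parents[0], parents[1], small_layout, rng)
            G = genotype_matrix(list(spores), markers)
            assert np.all(G.sum(axis=1) == 2)

    def test_mismatched_layout_errors(self, small_layout, parents):
        other = GenomeLayout(names=("chrX",), lengths=(1000,))
        stranger = HaplotypeMosaic.uniform(other, SUPERIOR)
        with pytest.raises(ValueError):
            meiosis(parents[0], stranger, small_layout, 0)


# ---------------------------------------------------------------------------
# inbreeding


class TestInbreed:
    def test_rounds_zero_returns_f1_spores(self, small_layout, parents):
        segs = inbreed([parents], 0, small_layout, seed=1, n_spores=40)
        assert len(segs) == 40
        markers = make_parental_markers(small_layout, 100, seed=1)
        G = genotype_matrix(segs, markers)
        # complementary tetrads in order -> overall allele balance exact
        assert G.mean() == pytest.approx(0.5, abs=0.01)

    def test_six_rounds_yields_population(self, small_layout, parents):
        segs = inbreed([parents], 6, small_layout, seed=2, n_spores=64)
        assert len(segs) == 64

    def test_block_length_decreases_with_rounds(self, small_layout, parents):
        """Inbreeding fragments parental blocks: F7 blocks shorter than F1."""
        f1 = inbreed([parents], 0, small_layout, seed=3, n_spores=200)
        f7 = inbreed([parents], 6, small_layout, seed=3, n_spores=200)
        m1 = np.mean([s.mean_block_length() for s in f1])
        m7 = np.mean([s.mean_block_length() for s in f7])
        assert m7 < m1

    def test_allele_frequency_conserved_without_selection(self, small_layout, parents):
        """Unselected inbreeding keeps allele frequency centred on 0.5.

        The genome median stays within 3 binomial standard errors and at
        least 95% of markers do individually (a handful of 3-SE excursions
        is expected even for perfectly binomial sampling, and linked
        markers drift together).
        """
        markers = make_parental_markers(small_layout, 300, seed=4)
        segs = inbreed([parents], 3, small_layout, seed=4, n_spores=256)
        G = genotype_matrix(segs, markers)
        freq = G.mean(axis=1)
        se = np.sqrt(0.25 / len(segs))
        assert abs(np.median(freq) - 0.5) <= 3 * se
        assert np.mean(np.abs(freq - 0.5) <= 3 * se) >= 0.95

    def test_empty_population_errors(self, small_layout):
        with pytest.raises(ValueError):
            inbreed([], 1, small_layout, seed=0)

    def test_determinism(self, small_layout, parents):
        a = inbreed([parents], 2, small_layout, seed=9, n_spores=32)
        b = inbreed([parents], 2, small_layout, seed=9, n_spores=32)
        assert all(x == y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# phenotype


class TestPhenotype:
    def test_null_architecture_gives_baseline(self, small_layout, parents):
        spec = PhenotypeSpec(loci=(), baseline=2.5, noise_sd=0.0)
        assert assign_phenotype(parents[0], spec, 0) == 2.5

    def test_additive_saturation(self, small_layout, parents):
        spec = PhenotypeSpec(
            loci=(CausalLocus("chrA", 1000, 1.0), CausalLocus("chrB", 5000, 0.5)),
            baseline=1.0,
            noise_sd=0.0,
        )
        assert assign_phenotype(parents[0], spec, 0) == pytest.approx(2.5)
        assert assign_phenotype(parents[1], spec, 0) == pytest.approx(1.0)

    def test_redundant_group_is_max_over_members(self, small_layout):
        """Carrying A only, B only, or both gives identical noiseless scores."""
        spec = PhenotypeSpec(
            loci=(CausalLocus("chrA", 1000, 1.0), CausalLocus("chrB", 5000, 1.0)),
            architecture="redundant",
            groups=((0, 1),),
            noise_sd=0.0,
        )
        def mosaic(a_label, b_label, lay):
            return HaplotypeMosaic.from_blocks(
                lay,
                {"chrA": [(300_000.0, a_label)], "chrB": [(200_000.0, b_label)]},
            )
        lay = GenomeLayout(names=("chrA", "chrB"), lengths=(300_000, 200_000))
        scores = {
            (a, b): assign_phenotype(mosaic(a, b, lay), spec, 0)
            for a in (SUPERIOR, INFERIOR)
            for b in (SUPERIOR, INFERIOR)
        }
        assert scores[(SUPERIOR, INFERIOR)] == scores[(INFERIOR, SUPERIOR)] == scores[(SUPERIOR, SUPERIOR)] == 1.0
        assert scores[(INFERIOR, INFERIOR)] == 0.0

    def test_noise_is_deterministic_given_seed(self, small_layout, parents):
        spec = PhenotypeSpec(loci=(), noise_sd=1.0)
        assert assign_phenotype(parents[0], spec, 5) == assign_phenotype(parents[0], spec, 5)


# ---------------------------------------------------------------------------
# selection


class TestSelectTop:
    def test_whole_population_ranked(self, small_layout, parents):
        pop = [parents[0], parents[1], parents[0]]
        sel = select_top(pop, np.array([1.0, 3.0, 2.0]), 3)
        assert list(sel.scores) == [3.0, 2.0, 1.0]

    def test_small_enumeration(self, small_layout, parents):
        pop = [parents[0]] * 3
        sel = select_top(pop, np.array([3.0, 1.0, 2.0]), 2)
        assert list(sel.scores) == [3.0, 2.0]
        assert list(sel.indices) == [0, 2]

    def test_ties_stable(self, small_layout, parents):
        pop = [parents[0]] * 3
        sel = select_top(pop, np.array([1.0, 1.0, 1.0]), 2)
        assert list(sel.indices) == [0, 1]

    def test_k_too_large_errors(self, small_layout, parents):
        with pytest.raises(ValueError):
            select_top([parents[0]], np.array([1.0]), 2)

    def test_paper_scale_selection_signal(self, small_layout, parents):
        """All of the 27-of-288 selected carry the superior causal allele."""
        pop = inbreed([parents], 0, small_layout, seed=6, n_spores=288)
        spec = PhenotypeSpec(loci=(CausalLocus("chrA", 150_000, 1.0),), noise_sd=0.0)
        scores = assign_phenotypes(pop, spec, 6)
        sel = select_top(pop, scores, 27)
        assert len(sel) == 27
        at = np.array([s.origin_at("chrA", np.array([150_000]))[0] for s in sel.segregants])
        assert np.all(at == SUPERIOR)


# ---------------------------------------------------------------------------
# sequencing


def _selection_of(segs):
    return Selection(segs, np.zeros(len(segs)), np.arange(len(segs)))


class TestSequencing:
    def test_noiseless_fixation(self, small_layout, parents):
        markers = make_parental_markers(small_layout, 50, seed=7)
        spec = SequencingSpec(mean_depth=30, error_rate=0.0)
        acm = sequence_pool(_selection_of([parents[0]] * 4), markers, spec, seed=7)
        assert np.all(acm.inf == 0)
        assert np.all(acm.sup == acm.coverage())

    def test_zero_depth_uncovered(self, small_layout, parents):
        markers = make_parental_markers(small_layout, 20, seed=7)
        spec = SequencingSpec(mean_depth=0)
        acm = sequence_pool(_selection_of([parents[0]]), markers, spec, seed=7)
        assert np.all(acm.coverage() == 0)

    def test_unselected_pool_near_half(self, small_layout, parents):
        """Unselected pool of a cross: superior read fraction ~0.5 genome-wide."""
        markers = make_parental_markers(small_layout, 400, seed=8)
        pop = inbreed([parents], 0, small_layout, seed=8, n_spores=200)
        spec = SequencingSpec(mean_depth=100, error_rate=0.0)
        acm = sequence_pool(_selection_of(pop), markers, spec, seed=8)
        f = acm.sup[:, 0] / acm.coverage()[:, 0]
        se = np.sqrt(0.25 * (1 / len(pop) + 1 / 100))
        assert abs(np.median(f) - 0.5) < 3 * se

    def test_individual_counts_monoallelic_without_error(self, small_layout, parents):
        markers = make_parental_markers(small_layout, 30, seed=9)
        spec = SequencingSpec(mean_depth=20, error_rate=0.0)
        acm = sequence_segregants(_selection_of(list(parents)), markers, spec, seed=9)
        assert acm.sup.shape == (30, 2)
        covered = acm.coverage() > 0
        mono = (acm.sup == 0) | (acm.inf == 0)
        assert np.all(mono[covered])

    def test_27_segregants_give_27_columns(self, small_layout, parents):
        markers = make_parental_markers(small_layout, 10, seed=9)
        segs = inbreed([parents], 0, small_layout, seed=9, n_spores=27)
        acm = sequence_segregants(_selection_of(segs), markers, SequencingSpec(), seed=9)
        assert len(acm.samples) == 27

    def test_individual_sum_approximates_pool(self, small_layout, parents):
        """Summing per-segregant counts matches pooled allele fractions."""
        markers = make_parental_markers(small_layout, 300, seed=10)
        segs = inbreed([parents], 0, small_layout, seed=10, n_spores=24)
        sel = _selection_of(segs)
        spec = SequencingSpec(mean_depth=40, error_rate=0.0)
        pool = sequence_pool(sel, markers, spec, seed=11)
        indiv = sequence_segregants(sel, markers, spec, seed=12)
        f_pool = pool.sup[:, 0] / np.maximum(pool.coverage()[:, 0], 1)
        cov_i = indiv.coverage().sum(axis=1)
        f_sum = indiv.sup.sum(axis=1) / np.maximum(cov_i, 1)
        # both estimate the same true pool fraction; the pooled read depth
        # (~40) dominates the sampling error of the difference
        resid = f_pool - f_sum
        sigma = np.sqrt(0.25 / 40)
        assert abs(resid.mean()) < 3 * sigma / np.sqrt(len(resid))
        assert np.mean(np.abs(resid)) < sigma

    def test_determinism_bit_for_bit(self, small_layout, parents):
        markers = make_parental_markers(small_layout, 50, seed=13)
        sel = _selection_of(list(parents))
        a = sequence_pool(sel, markers, SequencingSpec(), seed=13)
        b = sequence_pool(sel, markers, SequencingSpec(), seed=13)
        assert np.array_equal(a.sup, b.sup) and np.array_equal(a.qual, b.qual)
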