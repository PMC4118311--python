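import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gametevar import (PhasedGenotypes, SegmentMap, SNPEffectSet,
                       build_segment_map, exclude_region,
                       haplotype_breeding_values, selection_limit)
from gametevar.haplotypes import MarkerTable

from conftest import make_markers, random_phased


class TestSegmentMap:
    def test_partition_covers_every_snp_once(self):
        markers = make_markers(3, 17)
        sm = build_segment_map(markers, 11)
        seg = sm.snp_to_segment()
        assert sm.n_segments == 11
        assert sm.n_snps == markers.n_markers
        # every SNP in exactly one segment
        counts = np.zeros(markers.n_markers)
        for s in range(sm.n_segments):
            counts[sm.start[s]:sm.end[s]] += 1
        assert np.all(counts == 1)
        assert np.all(markers.chrom[sm.start] == sm.chrom)

    def test_one_segment_per_chromosome_degenerate(self):
        markers = make_markers(4, 5)
        sm = build_segment_map(markers, 4)
        assert sm.n_segments == 4
        assert np.all(sm.end - sm.start == 5)
        assert np.all(sm.recomb_to_next == 0)

    def test_equal_weights_fall_back_to_equal_counts(self):
        markers = make_markers(1, 10)
        sm = build_segment_map(markers, 2, hotspot_weights=np.ones(9))
        assert list(sm.end - sm.start) == [5, 5]

    def test_hotspot_weights_place_boundaries(self):
        markers = make_markers(1, 10)
        w = np.zeros(9)
        w[2] = 5.0  # interval between SNPs 2 and 3
        sm = build_segment_map(markers, 2, hotspot_weights=w)
        assert list(sm.start) == [0, 3]

    def test_too_few_segments_rejected(self):
        markers = make_markers(3, 5)
        with pytest.raises(ValueError):
            build_segment_map(markers, 2)

    def test_chip_scale_partition(self):
        # 29 autosomes, SNP counts summing to 43586, 1856 segments
        rng = np.random.default_rng(0)
        counts = rng.multinomial(43586 - 29 * 100, np.full(29, 1 / 29)) + 100
        chrom = np.repeat(np.arange(1, 30), counts)
        pos = np.concatenate([np.arange(c) + 1 for c in counts])
        ids = np.array([f"s{i}" for i in range(43586)], dtype=object)
        markers = MarkerTable(ids, chrom, pos,
                              np.full(43586, "A", object), np.full(43586, "B", object))
        sm = build_segment_map(markers, 1856)
        assert sm.n_segments == 1856
        assert sm.n_snps == 43586

    def test_recomb_probabilities_bounded(self):
        markers = make_markers(2, 30)
        sm = build_segment_map(markers, 12)
        assert np.all((sm.recomb_to_next >= 0) & (sm.recomb_to_next <= 0.5))


class TestHaplotypeBreedingValues:
    def test_hand_computed_segment_sum(self):
        markers = make_markers(1, 3)
        alleles = np.zeros((1, 3, 2), dtype=np.uint8)
        alleles[0, :, 0] = [1, 0, 1]
        phased = PhasedGenotypes(["x"], alleles)
        eff = SNPEffectSet("t", [0.4, -0.2, 0.6])
        sm = build_segment_map(markers, 1)
        tab = haplotype_breeding_values(phased, eff, sm)
        assert tab.values[0, 0, 0] == pytest.approx(0.5)  # 0.4/2 + 0.6/2
        assert tab.values[0, 0, 1] == 0.0

    def test_zero_and_homozygous_animals(self, rng):
        markers = make_markers(2, 10)
        alleles = np.zeros((2, 20, 2), dtype=np.uint8)
        hom = (rng.random(20) < 0.5).astype(np.uint8)
        alleles[1, :, 0] = alleles[1, :, 1] = hom
        phased = PhasedGenotypes(["zero", "hom"], alleles)
        eff = SNPEffectSet("t", rng.normal(size=20))
        tab = haplotype_breeding_values(phased, eff, build_segment_map(markers, 4))
        assert np.all(tab.values[0] == 0)
        assert np.allclose(tab.values[1, :, 0], tab.values[1, :, 1])

    def test_segment_sum_equals_direct_genomic_value(self, small_genome):
        _, phased, effects, segmap = small_genome
        tab = haplotype_breeding_values(phased, effects, segmap)
        dgv = phased.dosages() @ (effects.effects / 2.0)
        assert np.allclose(tab.values.sum(axis=(1, 2)), dgv)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_linearity_in_effects(self, seed):
        rng = np.random.default_rng(seed)
        markers = make_markers(2, 6)
        phased = random_phased(rng, 2, 12)
        sm = build_segment_map(markers, 4)
        e1, e2 = rng.normal(size=12), rng.normal(size=12)
        t1 = haplotype_breeding_values(phased, SNPEffectSet("t", e1), sm)
        t2 = haplotype_breeding_values(phased, SNPEffectSet("t", e2), sm)
        t12 = haplotype_breeding_values(phased, SNPEffectSet("t", e1 + e2), sm)
        assert np.allclose(t12.values, t1.values + t2.values)

    def test_dimension_mismatch_rejected(self, small_genome):
        _, phased, effects, segmap = small_genome
        with pytest.raises(ValueError):
            haplotype_breeding_values(phased, SNPEffectSet("t", effects.effects[:-1]), segmap)


class TestSelectionLimit:
    def test_exhaustive_per_segment_maxima(self):
        values = np.array([[[0.7, 0.1], [0.0, 0.2]],
                           [[0.3, 0.2], [0.3, 0.1]]])
        from gametevar.haplotypes import HaplotypeBVTable

        tab = HaplotypeBVTable("t", ["a", "b"], values)
        lim = selection_limit(tab)
        assert lim.gamete_limit == pytest.approx(0.7 + 0.3)
        assert lim.animal_limit == pytest.approx(2.0)

    def test_homozygous_single_animal_limit_is_mgbv(self, rng):
        from gametevar import RecombinationModel, analytic_gamete_moments
        from gametevar.haplotypes import HaplotypeBVTable

        markers = make_markers(2, 4)
        sm = build_segment_map(markers, 4)
        h = np.repeat(rng.normal(size=(1, 4, 1)), 2, axis=2)
        tab = HaplotypeBVTable("t", ["a"], h)
        lim = selection_limit(tab)
        st_ = analytic_gamete_moments(tab.values[0], sm, RecombinationModel())
        assert lim.gamete_limit == pytest.approx(st_.mgbv)

    def test_invariant_under_permutation_and_split(self, small_genome, rng):
        _, phased, effects, segmap = small_genome
        tab = haplotype_breeding_values(phased, effects, segmap)
        lim = selection_limit(tab)
        perm = rng.permutation(tab.n_animals)
        from gametevar.haplotypes import HaplotypeBVTable

        tab_p = HaplotypeBVTable("t", [tab.animal_ids[i] for i in perm],
                                 tab.values[perm])
        assert selection_limit(tab_p).gamete_limit == pytest.approx(lim.gamete_limit)
        # splitting a segment in two leaves the limit unchanged
        finer = build_segment_map(small_genome[0], segmap.n_segments + 1)
        tab_f = haplotype_breeding_values(phased, effects, finer)
        assert selection_limit(tab_f).gamete_limit >= lim.gamete_limit - 1e-12

    def test_dominates_sampled_gametes(self, small_genome):
        from gametevar import RecombinationModel, sample_gametes

        _, phased, effects, segmap = small_genome
        tab = haplotype_breeding_values(phased, effects, segmap)
        lim = selection_limit(tab)
        for i in range(tab.n_animals):
            s = sample_gametes(tab.values[i], segmap, RecombinationModel(), 500, 7)
            assert s.max() <= lim.gamete_limit + 1e-12


class TestExcludeRegion:
    def test_empty_region_is_identity_with_warning(self, small_genome):
        markers, phased, effects, segmap = small_genome
        base = haplotype_breeding_values(phased, effects, segmap)
        with pytest.warns(UserWarning):
            out = exclude_region(phased, effects, segmap, markers, 1,
                                 10_000_000, 20_000_000)
        assert np.allclose(out.values, base.values)

    def test_full_segment_exclusion_zeroes_it(self, small_genome):
        markers, phased, effects, segmap = small_genome
        out = exclude_region(phased, effects, segmap, markers, 1, 0, 10**9)
        chrom1 = segmap.chrom == 1
        assert np.all(out.values[:, chrom1, :] == 0)
        chrom2 = ~chrom1
        base = haplotype_breeding_values(phased, effects, segmap)
        assert np.allclose(out.values[:, chrom2, :], base.values[:, chrom2, :])

    def test_bad_chromosome_rejected(self, small_genome):
        markers, phased, effects, segmap = small_genome
        with pytest.raises(ValueError):
            exclude_region(phased, effects, segmap, markers, 99, 0, 1)
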