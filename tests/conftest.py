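import numpy as np
import pytest

from gametevar import (MarkerTable, PhasedGenotypes, SegmentMap, SNPEffectSet,
                       build_segment_map)


def make_markers(n_chrom=2, snps_per_chrom=10, spacing=100_000):
    chrom = np.repeat(np.arange(1, n_chrom + 1), snps_per_chrom)
    pos = np.tile((np.arange(snps_per_chrom) + 1) * spacing, n_chrom)
    ids = np.array([f"m{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return MarkerTable(ids, chrom, pos,
                       np.full(len(ids), "A", dtype=object),
                       np.full(len(ids), "B", dtype=object))


def random_phased(rng, n_animals, n_markers, freq=0.5):
    alleles = (rng.random((n_animals, n_markers, 2)) < freq).astype(np.uint8)
    return PhasedGenotypes([f"a{i}" for i in range(n_animals)], alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome(rng):
    """2 chromosomes x 10 SNPs, 3 animals, one trait, 4 segments."""
    markers = make_markers(2, 10)
    phased = random_phased(rng, 3, markers.n_markers)
    effects = SNPEffectSet("trait", rng.normal(0, 0.1, markers.n_markers), 1.0)
    segmap = build_segment_map(markers, 4)
    return markers, phased, effects, segmap
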