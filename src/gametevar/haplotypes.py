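"""Chromosome-segment maps and per-segment haplotype breeding values.

The central quantity of this package is the breeding value carried by a
single parental haplotype over a chromosome segment,

    h_{i,j} = sum_k z_{k,j} * (effect_k / 2),

where ``z`` is the 0/1 alternate-allele indicator of marker ``k`` on phase
``j`` (paternal or maternal) and the per-allele effect is half the
allele-substitution effect, so that the two transmitted haplotypes of a
mating sum to the offspring's direct genomic value.  Effects are stored as
full allele-substitution estimates; the halving happens inside the
operations, never in the stored data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PATERNAL = "paternal"
MATERNAL = "maternal"
UNKNOWN = "unknown"


@dataclass
class MarkerTable:
    """Ordered biallelic SNP map: id, chromosome, base-pair position, alleles.

    Markers must be sorted by (chromosome, position) with strictly
    increasing positions within a chromosome and unique ids; genome
    positions are 1-based as in VCF, SNP indices 0-based.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.ids.size == 0:
            raise ValueError("marker table is empty")
        if len({len(a) for a in (self.ids, self.chrom, self.pos, self.ref, self.alt)}) != 1:
            raise ValueError("marker table columns have inconsistent lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("marker ids are not unique")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(self.ids))):
            raise ValueError("markers must be sorted by (chromosome, position)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @property
    def chromosomes(self) -> np.ndarray:
        """Chromosome labels in genome order."""
        _, idx = np.unique(self.chrom, return_index=True)
        return self.chrom[np.sort(idx)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"marker_id": self.ids, "chrom": self.chrom, "pos": self.pos,
             "ref": self.ref, "alt": self.alt}
        )

    @classmethod
    def from_frame(cls, df) -> "MarkerTable":
        return cls(df["marker_id"].to_numpy(), df["chrom"].to_numpy(),
                   df["pos"].to_numpy(), df["ref"].to_numpy(), df["alt"].to_numpy())


@dataclass
class PhasedGenotypes:
    """Phased alleles for a set of animals: (animals, markers, 2 phases) 0/1.

    ``origin[a, j]`` records whether phase slot ``j`` of animal ``a`` is the
    paternal or maternal haplotype; ``unknown`` when phasing carries no
    parental-origin information.  By convention slot 0 is paternal whenever
    the origin is known.
    """

    animal_ids: list
    alleles: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.animal_ids = list(self.animal_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (animals, markers, 2)")
        if self.alleles.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length does not match allele matrix")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.origin is None:
            self.origin = np.full((len(self.animal_ids), 2), UNKNOWN, dtype=object)
        else:
            self.origin = np.asarray(self.origin, dtype=object)
            if self.origin.shape != (len(self.animal_ids), 2):
                raise ValueError("origin must have shape (animals, 2)")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, animal_id: str) -> int:
        return self.animal_ids.index(animal_id)

    def dosages(self) -> np.ndarray:
        """0/1/2 alternate-allele counts, (animals, markers)."""
        return self.alleles.sum(axis=2).astype(np.int64)

    def subset(self, animal_ids: Sequence[str]) -> "PhasedGenotypes":
        idx = [self.index_of(a) for a in animal_ids]
        return PhasedGenotypes(list(animal_ids), self.alleles[idx], self.origin[idx])


@dataclass
class SNPEffectSet:
    """Estimated allele-substitution effects for one trait.

    ``sigma_a`` is the trait's additive genetic standard deviation, used to
    express gamete statistics in sigma_a units when present.
    """

    trait: str
    effects: np.ndarray
    sigma_a: float | None = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.effects.ndim != 1:
            raise ValueError("effects must be one-dimensional")
        if self.sigma_a is not None and not self.sigma_a > 0:
            raise ValueError("sigma_a must be positive")


@dataclass
class SegmentMap:
    """Partition of the SNP genome into contiguous recombination segments.

    ``start``/``end`` are 0-based half-open SNP index ranges;
    ``recomb_to_next[s]`` is the recombination probability between segment
    ``s`` and ``s+1`` on the same chromosome (0 and unused on the final
    segment of each chromosome).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    recomb_to_next: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.recomb_to_next = np.asarray(self.recomb_to_next, dtype=np.float64)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.recomb_to_next) == n):
            raise ValueError("segment map columns have inconsistent lengths")
        if n == 0:
            raise ValueError("segment map is empty")
        if np.any(self.end <= self.start):
            raise ValueError("segments must be non-empty half-open ranges")
        if self.start[0] != 0 or np.any(self.start[1:] != self.end[:-1]):
            raise ValueError("segments must be contiguous and ordered")
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("segments must be ordered by chromosome")
        if np.any((self.recomb_to_next < 0) | (self.recomb_to_next > 0.5)):
            raise ValueError("recombination probabilities must lie in [0, 0.5]")

    @property
    def n_segments(self) -> int:
        return len(self.chrom)

    @property
    def n_snps(self) -> int:
        return int(self.end[-1])

    def chromosome_slices(self) -> list:
        """[(chrom, segment index slice)] in genome order."""
        out = []
        s = 0
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            out.append((int(c), slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def snp_to_segment(self) -> np.ndarray:
        """Segment index of each SNP, length n_snps."""
        seg = np.empty(self.n_snps, dtype=np.int64)
        for s in range(self.n_segments):
            seg[self.start[s]:self.end[s]] = s
        return seg

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"segment": np.arange(self.n_segments), "chrom": self.chrom,
             "start_snp": self.start, "end_snp": self.end,
             "recomb_to_next": self.recomb_to_next}
        )


@dataclass
class HaplotypeBVTable:
    """Per animal x segment x phase haplotype breeding values ``h_{i,j}``."""

    trait: str
    animal_ids: list
    values: np.ndarray  # (animals, segments, 2)

    def __post_init__(self) -> None:
        self.animal_ids = list(self.animal_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("values must have shape (animals, segments, 2)")
        if self.values.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length does not match value table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("haplotype breeding values must be finite")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    def row(self, animal_id: str) -> np.ndarray:
        return self.values[self.animal_ids.index(animal_id)]

    def direct_genomic_values(self) -> np.ndarray:
        """Sum of both phases over all segments (halved-effect scale)."""
        return self.values.sum(axis=(1, 2))


def poisson_junction_prob(rate: float, n_junctions: int) -> float:
    """Per-junction flip probability implied by Poisson(rate) crossovers
    placed uniformly over ``n_junctions`` junctions (probability of an odd
    count at one junction; Haldane on equal sub-lengths)."""
    if n_junctions <= 0:
        return 0.0
    return 0.5 * (1.0 - math.exp(-2.0 * rate / n_junctions))


def _equal_count_boundaries(counts, offsets, n_segments) -> list:
    """Internal boundary SNP indices for as-equal-as-possible SNP blocks,
    segments allocated to chromosomes by largest remainder (>=1 each)."""
    quota = counts / counts.sum() * n_segments
    alloc = np.maximum(1, np.floor(quota).astype(int))
    alloc = np.minimum(alloc, counts)
    while alloc.sum() < n_segments:
        room = alloc < counts
        frac = np.where(room, quota - alloc, -np.inf)
        alloc[int(np.argmax(frac))] += 1
    while alloc.sum() > n_segments:
        frac = np.where(alloc > 1, quota - alloc, np.inf)
        alloc[int(np.argmin(frac))] -= 1
    boundaries: list[int] = []
    for ci in range(len(counts)):
        cuts = np.linspace(0, counts[ci], alloc[ci] + 1).round().astype(int)
        boundaries.extend((offsets[ci] + cuts[1:-1]).tolist())
    return boundaries


def build_segment_map(
    markers: MarkerTable,
    n_segments: int,
    hotspot_weights: np.ndarray | None = None,
    crossover_rate: float = 0.3,
) -> SegmentMap:
    """Partition the marker genome into ``n_segments`` contiguous segments.

    Chromosome ends are always boundaries.  Without weights, segments are
    allocated to chromosomes proportionally to SNP count and split into
    as-equal-as-possible SNP blocks.  With per-interval ``hotspot_weights``
    (one per inter-SNP interval within chromosomes, genome order), internal
    boundaries are placed at the highest-weight intervals — mirroring
    segmentation on an empirical crossover hotspot map.

    ``recomb_to_next`` is filled with the Poisson(crossover_rate)-implied
    per-junction probability for each chromosome.
    """
    chroms = markers.chromosomes
    n_chrom = len(chroms)
    if n_segments < n_chrom:
        raise ValueError("n_segments must be at least the number of chromosomes")
    counts = np.array([(markers.chrom == c).sum() for c in chroms])
    offsets = np.concatenate([[0], np.cumsum(counts)])

    equal = _equal_count_boundaries(counts, offsets, n_segments)
    if hotspot_weights is not None:
        w = np.asarray(hotspot_weights, dtype=np.float64)
        n_internal = markers.n_markers - n_chrom
        if w.shape != (n_internal,):
            raise ValueError(
                f"hotspot_weights must have one entry per within-chromosome "
                f"inter-SNP interval ({n_internal})")
        if np.any(w < 0):
            raise ValueError("hotspot_weights must be non-negative")
        # interval i sits between within-chromosome SNP pairs; map to the
        # genome-wide index of the SNP that would start a new segment
        interval_to_snp = np.concatenate(
            [np.arange(offsets[ci] + 1, offsets[ci + 1]) for ci in range(n_chrom)]
        ) if n_internal else np.empty(0, dtype=np.int64)
        k = n_segments - n_chrom
        # ties in weight fall back to equal-SNP-count placement
        not_equal_cut = np.array([s not in set(equal) for s in interval_to_snp], dtype=int)
        order = np.lexsort((np.arange(n_internal), not_equal_cut, -w))
        boundaries = sorted(interval_to_snp[order[:k]].tolist())
    else:
        boundaries = equal

    starts = np.sort(np.unique(np.concatenate(
        [offsets[:-1], np.asarray(boundaries, dtype=np.int64)]))).astype(np.int64)
    if len(starts) != n_segments:
        raise ValueError("could not place the requested number of segments "
                         "(tied or duplicate boundary intervals)")
    ends = np.concatenate([starts[1:], [markers.n_markers]])
    seg_chrom = markers.chrom[starts]

    recomb = np.zeros(len(starts))
    for c in chroms:
        idx = np.flatnonzero(seg_chrom == c)
        J = len(idx) - 1
        r = poisson_junction_prob(crossover_rate, J)
        recomb[idx[:-1]] = r
    return SegmentMap(seg_chrom, starts, ends, recomb)


def haplotype_breeding_values(
    phased: PhasedGenotypes, effects: SNPEffectSet, segmap: SegmentMap
) -> HaplotypeBVTable:
    """Compute h = sum_k z_k * (effect_k / 2) per animal, segment and phase."""
    if phased.n_markers != len(effects.effects):
        raise ValueError("effects length does not match marker count")
    if segmap.n_snps != phased.n_markers:
        raise ValueError("segment map does not cover the marker set")
    alpha = effects.effects / 2.0
    weighted = phased.alleles * alpha[None, :, None]
    values = np.add.reduceat(weighted, segmap.start, axis=1)
    return HaplotypeBVTable(effects.trait, phased.animal_ids, values)


@dataclass
class SelectionLimit:
    """Theoretical best gamete/animal assembled from the best observed
    haplotype in every segment."""

    trait: str
    gamete_limit: float
    animal_limit: float
    best_animal: np.ndarray = field(default=None, repr=False)  # per-segment argmax (animal, phase)


def selection_limit(hapbv: HaplotypeBVTable) -> SelectionLimit:
    """Sum of the per-segment maxima over all animals and phases."""
    if hapbv.n_animals < 1:
        raise ValueError("selection limit requires at least one animal")
    flat = hapbv.values.transpose(1, 0, 2).reshape(hapbv.n_segments, -1)
    best = flat.argmax(axis=1)
    g = float(flat.max(axis=1).sum())
    picks = np.stack([best // 2, best % 2], axis=1)
    return SelectionLimit(hapbv.trait, g, 2.0 * g, picks)


def exclude_region(
    phased: PhasedGenotypes,
    effects: SNPEffectSet,
    segmap: SegmentMap,
    markers: MarkerTable,
    chrom: int,
    start_bp: int,
    end_bp: int,
) -> HaplotypeBVTable:
    """Recompute haplotype breeding values with all SNPs in the closed
    base-pair interval [start_bp, end_bp] on ``chrom`` removed (their
    effects treated as absent); the segment structure is unchanged.

    Used to quantify how much a large-effect region (e.g. a DGAT1-like
    locus) contributes to gametic variance.
    """
    if chrom not in markers.chromosomes:
        raise ValueError(f"chromosome {chrom} not present in the marker table")
    mask = (markers.chrom == chrom) & (markers.pos >= start_bp) & (markers.pos <= end_bp)
    if not mask.any():
        warnings.warn("exclusion region covers no SNPs; result is unchanged")
    kept = effects.effects.copy()
    kept[mask] = 0.0
    return haplotype_breeding_values(
        phased, SNPEffectSet(effects.trait, kept, effects.sigma_a), segmap
    )
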