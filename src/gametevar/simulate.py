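"""Gene-dropping population simulator with per-meiosis truth records.

Founders are drawn in Hardy-Weinberg equilibrium (linkage equilibrium by
default) at configurable allele frequencies; descendants are produced by
simulated meioses that use the very same segment-junction crossover process
as the gamete sampler, so predicted gamete moments can be checked against
truth-recorded transmissions.  Trait effects are drawn normally and scaled
so the founder additive SD is one (sigma_a = 1 unit); "reliability" of a
trait shrinks the estimated effects toward zero relative to the true ones,
emulating the smaller predicted gametic variation of poorly predicted
traits.  An optional large-effect locus at intermediate frequency creates a
DGAT1-like bimodal SDGBV distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gametes import RecombinationModel, _sample_phase_matrix
from .haplotypes import (MATERNAL, PATERNAL, MarkerTable, PhasedGenotypes,
                         SegmentMap, SNPEffectSet, build_segment_map)
from .relatedness import Pedigree


@dataclass
class MajorLocusSpec:
    """A single large-effect SNP (chromosome, SNP offset within it, allele
    substitution effect in sigma_a of the polygenic background, founder
    frequency)."""

    chrom: int = 1
    snp: int | None = None  # default: middle SNP of the chromosome
    effect: float = 0.8
    frequency: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.frequency < 1:
            raise ValueError("major-locus frequency must lie in (0, 1)")


@dataclass
class TraitSpec:
    """Simulated trait: effects ~ N(0, .), scaled to unit founder additive
    SD; estimated effects = reliability * true effects."""

    name: str = "protein"
    reliability: float = 0.69
    major_locus: MajorLocusSpec | None = None

    def __post_init__(self) -> None:
        if not 0 < self.reliability <= 1:
            raise ValueError("reliability must lie in (0, 1]")


@dataclass
class SimConfig:
    """Study design for the gene-dropping simulation."""

    n_founders: int = 200
    n_generations: int = 0
    offspring_per_generation: int = 200
    n_chromosomes: int = 10
    snps_per_chromosome: int = 40
    segments_per_chromosome: int = 4
    founder_freq_range: tuple = (0.05, 0.95)
    traits: tuple = (TraitSpec(),)
    recombination: RecombinationModel = field(default_factory=RecombinationModel)
    selection: str = "none"  # none | truncation-on-DGV | sires-only
    sire_fraction: float = 0.1
    dam_fraction: float = 0.5
    selection_trait: str | None = None  # default: first trait

    def __post_init__(self) -> None:
        for name, v in (("n_founders", self.n_founders),
                        ("offspring_per_generation", self.offspring_per_generation),
                        ("n_chromosomes", self.n_chromosomes),
                        ("snps_per_chromosome", self.snps_per_chromosome),
                        ("segments_per_chromosome", self.segments_per_chromosome)):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.selection not in ("none", "truncation-on-DGV", "sires-only"):
            raise ValueError(f"unknown selection rule: {self.selection!r}")
        lo, hi = self.founder_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("founder_freq_range must lie inside (0, 1)")


@dataclass
class SimPopulation:
    """Everything the downstream modules consume, plus ground truth."""

    markers: MarkerTable
    phased: PhasedGenotypes
    pedigree: Pedigree
    segmap: SegmentMap
    effects: dict  # trait -> SNPEffectSet (estimated, what the method sees)
    true_effects: dict  # trait -> SNPEffectSet
    truth: pd.DataFrame  # one row per meiosis
    founder_freqs: np.ndarray
    config: SimConfig


def _make_markers(config: SimConfig) -> MarkerTable:
    M = config.n_chromosomes * config.snps_per_chromosome
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1),
                      config.snps_per_chromosome)
    pos = np.tile(np.arange(1, config.snps_per_chromosome + 1) * 100_000,
                  config.n_chromosomes)
    ids = np.array([f"snp{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return MarkerTable(ids, chrom, pos,
                       np.full(M, "A", dtype=object), np.full(M, "B", dtype=object))


def _draw_effects(config: SimConfig, freqs: np.ndarray,
                  rng: np.random.Generator) -> tuple[dict, dict]:
    true, est = {}, {}
    for spec in config.traits:
        e = rng.normal(0.0, 1.0, size=len(freqs))
        # scale the polygenic background to unit additive SD in founders
        var = float(np.sum(2.0 * freqs * (1.0 - freqs) * e ** 2))
        e = e / np.sqrt(var)
        if spec.major_locus is not None:
            e[_locus_index(config, spec.major_locus)] = spec.major_locus.effect
        true[spec.name] = SNPEffectSet(spec.name, e, sigma_a=1.0)
        est[spec.name] = SNPEffectSet(spec.name, spec.reliability * e, sigma_a=1.0)
    return true, est


def _locus_index(config: SimConfig, locus: MajorLocusSpec) -> int:
    if not 1 <= locus.chrom <= config.n_chromosomes:
        raise ValueError("major locus chromosome out of range")
    snp = locus.snp if locus.snp is not None else config.snps_per_chromosome // 2
    if not 0 <= snp < config.snps_per_chromosome:
        raise ValueError("major locus SNP offset out of range")
    return (locus.chrom - 1) * config.snps_per_chromosome + snp


def _meiosis(rng, parent_alleles: np.ndarray, segmap: SegmentMap,
             model: RecombinationModel, snp_seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: (allele vector over SNPs, per-segment phase choices)."""
    phases = _sample_phase_matrix(rng, segmap, model, 1)[0]
    gamete = parent_alleles[np.arange(parent_alleles.shape[0]), phases[snp_seg]]
    return gamete.astype(np.uint8), phases


def simulate_population(config: SimConfig, seed: int) -> SimPopulation:
    """Run the gene-dropping simulation; fully reproducible by seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    markers = _make_markers(config)
    segmap = build_segment_map(
        markers, config.n_chromosomes * config.segments_per_chromosome,
        crossover_rate=config.recombination.rate)
    snp_seg = segmap.snp_to_segment()

    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=markers.n_markers)
    for spec in config.traits:
        if spec.major_locus is not None:
            freqs[_locus_index(config, spec.major_locus)] = spec.major_locus.frequency
    true_eff, est_eff = _draw_effects(config, freqs, rng)

    nf = config.n_founders
    alleles = [(rng.random((nf, markers.n_markers, 2)) < freqs[None, :, None]
                ).astype(np.uint8)]
    ids = [f"G0_{i:04d}" for i in range(nf)]
    sex = list(np.where(np.arange(nf) % 2 == 0, "M", "F"))
    rng.shuffle(sex)
    sire_idx = [-1] * nf
    dam_idx = [-1] * nf
    birth = [2000] * nf
    gen_members = [list(range(nf))]
    truth_rows: list[dict] = []
    all_alleles = alleles[0]

    sel_trait = config.selection_trait or config.traits[0].name
    half_eff = {t: s.effects / 2.0 for t, s in est_eff.items()}

    for g in range(1, config.n_generations + 1):
        prev = gen_members[-1]
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError("a generation lacks one sex; enlarge the population")
        if config.selection in ("truncation-on-DGV", "sires-only"):
            dgv = all_alleles.sum(axis=2).astype(float) @ half_eff[sel_trait]
            males = sorted(males, key=lambda i: -dgv[i])[
                :max(1, int(np.ceil(config.sire_fraction * len(males))))]
            if config.selection == "truncation-on-DGV":
                females = sorted(females, key=lambda i: -dgv[i])[
                    :max(1, int(np.ceil(config.dam_fraction * len(females))))]
        new_alleles = np.empty((config.offspring_per_generation,
                                markers.n_markers, 2), dtype=np.uint8)
        for o in range(config.offspring_per_generation):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            child = len(ids)
            cid = f"G{g}_{o:04d}"
            for role, parent in ((PATERNAL, s), (MATERNAL, d)):
                gam, phases = _meiosis(rng, all_alleles[parent], segmap,
                                       config.recombination, snp_seg)
                slot = 0 if role == PATERNAL else 1
                new_alleles[o, :, slot] = gam
                rec = {"parent": ids[parent], "offspring": cid, "role": role,
                       "phases": "".join(map(str, phases))}
                for t, a in half_eff.items():
                    rec[f"gamete_bv_{t}"] = float(gam @ a)
                truth_rows.append(rec)
            ids.append(cid)
            sire_idx.append(s)
            dam_idx.append(d)
            sex.append("M" if rng.random() < 0.5 else "F")
            birth.append(2000 + g)
        gen_members.append(list(range(len(ids) - config.offspring_per_generation,
                                      len(ids))))
        all_alleles = np.concatenate([all_alleles, new_alleles], axis=0)

    n = len(ids)
    origin = np.tile(np.array([PATERNAL, MATERNAL], dtype=object), (n, 1))
    origin[:nf] = "unknown"  # founder phases carry no parental labels
    phased = PhasedGenotypes(ids, all_alleles, origin)
    owners = np.array([f"owner{i % 5}" for i in range(n)], dtype=object)
    ped = Pedigree(ids, np.array(sire_idx), np.array(dam_idx),
                   np.array(birth), np.array(sex, dtype=object), owners)
    truth = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["parent", "offspring", "role", "phases"])
    return SimPopulation(markers, phased, ped, segmap, est_eff, true_eff,
                         truth, freqs, config)


def simulate_progeny_groups(
    config: SimConfig,
    offspring_counts: list[int],
    seed: int,
) -> SimPopulation:
    """Founder sires mated to founder dams with per-sire progeny-group
    sizes fixed by ``offspring_counts`` (sire i gets counts[i] offspring,
    each from a randomly drawn dam) — the design used for progeny-group
    validation studies."""
    pop = simulate_population(replace(config, n_generations=0), seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    males = [i for i, s in enumerate(pop.pedigree.sex) if s == "M"]
    females = [i for i, s in enumerate(pop.pedigree.sex) if s == "F"]
    if len(males) < len(offspring_counts):
        raise ValueError("not enough founder males for the requested sires")
    snp_seg = pop.segmap.snp_to_segment()
    half_eff = {t: s.effects / 2.0 for t, s in pop.effects.items()}

    ids = list(pop.phased.animal_ids)
    sire_idx = list(pop.pedigree.sire)
    dam_idx = list(pop.pedigree.dam)
    birth = list(pop.pedigree.birth_year)
    sex = list(pop.pedigree.sex)
    blocks = [pop.phased.alleles]
    truth_rows = []
    for si, count in enumerate(offspring_counts):
        s = males[si]
        block = np.empty((count, pop.markers.n_markers, 2), dtype=np.uint8)
        for o in range(count):
            d = females[rng.integers(len(females))]
            cid = f"O{si:03d}_{o:04d}"
            for role, parent, slot in ((PATERNAL, s, 0), (MATERNAL, d, 1)):
                gam, phases = _meiosis(rng, pop.phased.alleles[parent],
                                       pop.segmap, config.recombination, snp_seg)
                block[o, :, slot] = gam
                rec = {"parent": ids[parent], "offspring": cid, "role": role,
                       "phases": "".join(map(str, phases))}
                for t, a in half_eff.items():
                    rec[f"gamete_bv_{t}"] = float(gam @ a)
                truth_rows.append(rec)
            ids.append(cid)
            sire_idx.append(s)
            dam_idx.append(d)
            birth.append(2001)
            sex.append("F")
        blocks.append(block)
    alleles = np.concatenate(blocks, axis=0)
    n = len(ids)
    origin = np.tile(np.array([PATERNAL, MATERNAL], dtype=object), (n, 1))
    origin[:pop.config.n_founders] = "unknown"
    phased = PhasedGenotypes(ids, alleles, origin)
    owners = np.array([f"owner{i % 5}" for i in range(n)], dtype=object)
    ped = Pedigree(ids, np.array(sire_idx), np.array(dam_idx),
                   np.array(birth), np.array(sex, dtype=object), owners)
    truth = pd.concat([pop.truth, pd.DataFrame(truth_rows)], ignore_index=True)
    return SimPopulation(pop.markers, phased, ped, pop.segmap, pop.effects,
                         pop.true_effects, truth, pop.founder_freqs, config)


# ---------------------------------------------------------------------------
# deterministic fixtures

FIXTURE_VERSION = 1
_FIXTURE_SEED = 20140702


def make_fixtures(name: str):
    """Deterministic, versioned study datasets.

    tiny-trio
        3 animals (sire, dam, offspring), 2 chromosomes x 10 SNPs, for
        hand-checkable unit tests.
    two-bulls
        Synthetic parents whose analytic MGBV/SDGBV equal the published
        two-bull demonstration values exactly (bulls 1.81/0.29 and
        1.68/0.52; dams -1.40/0.44, 0.55/0.39, 2.12/0.32), plus the
        matching phased genotypes, effects and map-law segment map.
    selection-cohort
        Multi-generation population under sires-only truncation selection
        for trend, inbreeding and SDGBV-vs-F_G tests.
    """
    if name == "tiny-trio":
        cfg = SimConfig(n_founders=2, n_generations=1, offspring_per_generation=1,
                        n_chromosomes=2, snps_per_chromosome=10,
                        segments_per_chromosome=2,
                        traits=(TraitSpec("protein", reliability=1.0),))
        return simulate_population(cfg, _FIXTURE_SEED)
    if name == "two-bulls":
        return _two_bulls_fixture()
    if name == "selection-cohort":
        cfg = SimConfig(n_founders=200, n_generations=6,
                        offspring_per_generation=200,
                        n_chromosomes=10, snps_per_chromosome=60,
                        segments_per_chromosome=4,
                        selection="sires-only", sire_fraction=0.08,
                        traits=(TraitSpec("protein", reliability=0.69),))
        return simulate_population(cfg, _FIXTURE_SEED)
    raise ValueError(f"unknown fixture: {name!r}")


_TWO_BULLS_TARGETS = [
    ("bull1", 1.81, 0.29), ("bull2", 1.68, 0.52),
    ("dam_poor", -1.40, 0.44), ("dam_avg", 0.55, 0.39), ("dam_sup", 2.12, 0.32),
]


def _two_bulls_fixture():
    """Construct genotypes and a shared effect set whose analytic gamete
    moments reproduce the published parent values exactly.

    Each of the five animals owns a private chromosome (4 segments, 2 SNPs
    per segment: one heterozygous SNP driving d, one homozygous SNP driving
    m) on which every other animal carries reference alleles; the segment
    map uses map-law junction probabilities of 0.5, so segments segregate
    independently and SDGBV^2 = sum d_s^2 by design.  Synthetic stand-in
    for the paper's two real bulls.
    """
    K = 4  # segments (and private blocks) per animal
    n_animals = len(_TWO_BULLS_TARGETS)
    n_chrom = n_animals
    snps_per_chrom = 2 * K
    M = n_chrom * snps_per_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), snps_per_chrom)
    pos = np.tile(np.arange(1, snps_per_chrom + 1) * 1_000_000, n_chrom)
    ids = np.array([f"m{c}_{j}" for c, j in zip(chrom, pos)], dtype=object)
    markers = MarkerTable(ids, chrom, pos,
                          np.full(M, "A", dtype=object), np.full(M, "B", dtype=object))
    seg_chrom = np.repeat(np.arange(1, n_chrom + 1), K)
    start = np.arange(0, M, 2)
    end = start + 2
    recomb = np.where(np.arange(n_chrom * K) % K == K - 1, 0.0, 0.5)
    segmap = SegmentMap(seg_chrom, start, end, recomb)

    effects = np.zeros(M)
    alleles = np.zeros((n_animals, M, 2), dtype=np.uint8)
    for a, (name, mgbv, sdgbv) in enumerate(_TWO_BULLS_TARGETS):
        d = sdgbv / np.sqrt(K)  # per-segment gamete half-difference
        m = mgbv / K            # per-segment gamete mean contribution
        e_het = 4.0 * d         # h_pat - h_mat = e_het/2 -> d = e_het/4
        e_hom = 2.0 * m - e_het / 2.0
        for s in range(K):
            het = a * snps_per_chrom + 2 * s
            hom = het + 1
            effects[het] = e_het
            effects[hom] = e_hom
            alleles[a, het, 0] = 1  # heterozygous, alt on phase 0
            alleles[a, hom, :] = 1  # homozygous alt
    phased = PhasedGenotypes([n for n, _, _ in _TWO_BULLS_TARGETS], alleles)
    eff = SNPEffectSet("protein", effects, sigma_a=1.0)
    return {"markers": markers, "phased": phased, "effects": eff,
            "segmap": segmap, "model": RecombinationModel(law="map"),
            "targets": dict((n, (m, s)) for n, m, s in _TWO_BULLS_TARGETS),
            "version": FIXTURE_VERSION}
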