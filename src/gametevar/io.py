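"""File formats, QC filtering and the end-to-end pipeline.

Phased VCF (GT with '|' separators) is the canonical genotype interchange
format, read through cyvcf2; a simpler haplotype TSV dialect (two rows per
animal, version-headed) is provided for hand-built data.  Import applies
the standard chip QC: animals with call rate <= 0.98 are dropped, then
non-autosomal SNPs and SNPs with minor allele frequency <= 0.01; any
missing genotypes that survive are filled with the site's major allele and
counted in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import (MarkerTable, PhasedGenotypes, SegmentMap,
                         SNPEffectSet, build_segment_map,
                         haplotype_breeding_values)

HAP_TSV_MAGIC = "#gametevar-hap v1"

MIN_CALL_RATE = 0.98
MIN_MAF = 0.01


@dataclass
class QCReport:
    """Counts removed per import rule; retained + removed = input."""

    n_animals_in: int = 0
    n_animals_kept: int = 0
    n_animals_low_call_rate: int = 0
    n_snps_in: int = 0
    n_snps_kept: int = 0
    n_snps_low_maf: int = 0
    n_snps_non_autosomal: int = 0
    n_genotypes_filled: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(path, markers: MarkerTable, phased: PhasedGenotypes) -> None:
    """Write an uncompressed phased VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gametevar\n")
        for c in markers.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, phased.animal_ids)) + "\n")
        for k in range(markers.n_markers):
            gts = "\t".join(
                f"{phased.alleles[a, k, 0]}|{phased.alleles[a, k, 1]}"
                for a in range(phased.n_animals))
            fh.write(f"{markers.chrom[k]}\t{markers.pos[k]}\t{markers.ids[k]}"
                     f"\t{markers.ref[k]}\t{markers.alt[k]}\t.\tPASS\t.\tGT\t{gts}\n")


def _read_vcf_raw(path):
    """(animal ids, alleles int8 with -1 missing, marker frame). Raises on
    unphased non-missing genotypes or duplicate sample ids."""
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate animal id in VCF header")
    rows, alleles = [], []
    for var in v:
        g = np.asarray(var.genotype.array())
        if np.any((g[:, 0] >= 0) & (g[:, 1] >= 0) & (g[:, 2] == 0)):
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} ({var.ID}); "
                "phased input is required")
        alleles.append(g[:, :2].astype(np.int8))
        rows.append({"marker_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0] if var.ALT else "."})
    if not rows:
        raise ValueError(f"no variants in {path}")
    return samples, np.stack(alleles, axis=1), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# haplotype TSV dialect

def write_haplotypes_tsv(path, markers: MarkerTable, phased: PhasedGenotypes) -> None:
    """Two rows per animal: animal_id, phase label (P/M or 0/1), alleles."""
    lab = {0: "P", 1: "M"}
    with open(path, "w") as fh:
        fh.write(HAP_TSV_MAGIC + "\n")
        fh.write("animal_id\tphase\t" + "\t".join(map(str, markers.ids)) + "\n")
        for a, aid in enumerate(phased.animal_ids):
            for j in (0, 1):
                known = phased.origin[a, j] in ("paternal", "maternal")
                tag = lab[j] if known else str(j)
                fh.write(f"{aid}\t{tag}\t"
                         + "\t".join(map(str, phased.alleles[a, :, j])) + "\n")


def read_haplotypes_tsv(path, markers: MarkerTable) -> PhasedGenotypes:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != HAP_TSV_MAGIC:
            raise ValueError(f"not a gametevar haplotype TSV (header {magic!r})")
        header = fh.readline().rstrip("\n").split("\t")
        if header[2:] != list(map(str, markers.ids)):
            raise ValueError("haplotype TSV marker columns do not match the marker table")
        per_animal: dict[str, dict] = {}
        order = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            aid, tag = parts[0], parts[1]
            if aid not in per_animal:
                per_animal[aid] = {}
                order.append(aid)
            slot = {"P": 0, "0": 0, "M": 1, "1": 1}.get(tag)
            if slot is None:
                raise ValueError(f"bad phase label {tag!r} for animal {aid!r}")
            if slot in per_animal[aid]:
                raise ValueError(f"duplicate phase row for animal {aid!r}")
            per_animal[aid][slot] = (np.array(parts[2:], dtype=np.uint8),
                                     tag in ("P", "M"))
    alleles = np.empty((len(order), markers.n_markers, 2), dtype=np.uint8)
    origin = np.full((len(order), 2), "unknown", dtype=object)
    for a, aid in enumerate(order):
        if set(per_animal[aid]) != {0, 1}:
            raise ValueError(f"animal {aid!r} does not have exactly two phase rows")
        for j in (0, 1):
            alleles[a, :, j], labeled = per_animal[aid][j]
            if labeled:
                origin[a, j] = "paternal" if j == 0 else "maternal"
    return PhasedGenotypes(order, alleles, origin)


# ---------------------------------------------------------------------------
# QC + import

def _autosome_number(label) -> int | None:
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        return None  # X, Y, MT, ...


def import_genotypes(
    path,
    fmt: str = "vcf",
    markers: MarkerTable | None = None,
    min_call_rate: float = MIN_CALL_RATE,
    min_maf: float = MIN_MAF,
) -> tuple[PhasedGenotypes, MarkerTable, QCReport]:
    """Read phased genotypes and apply the import QC.

    Animals with call rate <= ``min_call_rate`` are dropped, then
    non-autosomal SNPs and SNPs with MAF <= ``min_maf`` (strict thresholds;
    a SNP at exactly 1% MAF is removed).  Residual missing genotypes are
    filled with the site's major allele.
    """
    if fmt == "vcf":
        samples, alleles, mdf = _read_vcf_raw(path)
    elif fmt == "hap-tsv":
        if markers is None:
            raise ValueError("hap-tsv import requires a marker table")
        pg = read_haplotypes_tsv(path, markers)
        samples = pg.animal_ids
        alleles = pg.alleles.astype(np.int8)
        mdf = markers.to_frame()
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")

    rep = QCReport(n_animals_in=len(samples), n_snps_in=mdf.shape[0])
    missing = alleles < 0
    call_rate = 1.0 - missing.any(axis=2).mean(axis=1)
    keep_a = call_rate > min_call_rate
    rep.n_animals_low_call_rate = int((~keep_a).sum())
    alleles = alleles[keep_a]
    samples = [s for s, k in zip(samples, keep_a) if k]
    if not samples:
        raise ValueError("no animals pass the call-rate filter")

    auto = np.array([_autosome_number(c) for c in mdf["chrom"]], dtype=object)
    keep_auto = np.array([a is not None for a in auto])
    rep.n_snps_non_autosomal = int((~keep_auto).sum())

    with np.errstate(invalid="ignore"):
        masked = np.ma.masked_less(alleles, 0)
        freq = masked.mean(axis=(0, 2)).filled(np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf > min_maf
    rep.n_snps_low_maf = int((keep_auto & ~keep_maf).sum())
    keep_s = keep_auto & keep_maf

    alleles = alleles[:, keep_s, :]
    freq = freq[keep_s]
    mdf = mdf.loc[keep_s].reset_index(drop=True)
    missing = alleles < 0
    rep.n_genotypes_filled = int(missing.any(axis=2).sum())
    if rep.n_genotypes_filled:
        fill = (freq >= 0.5).astype(np.int8)
        alleles = np.where(missing, fill[None, :, None], alleles)
    rep.n_animals_kept = len(samples)
    rep.n_snps_kept = int(keep_s.sum())
    out_markers = MarkerTable(
        mdf["marker_id"].to_numpy(),
        np.array([_autosome_number(c) for c in mdf["chrom"]]),
        mdf["pos"].to_numpy(), mdf["ref"].to_numpy(), mdf["alt"].to_numpy())
    return (PhasedGenotypes(samples, alleles.astype(np.uint8)), out_markers, rep)


# ---------------------------------------------------------------------------
# small tabular formats

def write_markers_tsv(path, markers: MarkerTable) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers_tsv(path) -> MarkerTable:
    return MarkerTable.from_frame(pd.read_csv(path, sep="\t"))


def write_effects_tsv(path, effect_sets: dict, markers: MarkerTable,
                      sigma_path=None) -> None:
    """Long-format effects TSV (marker_id, trait, effect) plus an optional
    sigma_a sidecar (trait, sigma_a)."""
    frames = [pd.DataFrame({"marker_id": markers.ids, "trait": t, "effect": e.effects})
              for t, e in effect_sets.items()]
    pd.concat(frames).to_csv(path, sep="\t", index=False)
    if sigma_path is not None:
        pd.DataFrame(
            [{"trait": t, "sigma_a": e.sigma_a} for t, e in effect_sets.items()
             if e.sigma_a is not None]
        ).to_csv(sigma_path, sep="\t", index=False)


def read_effects_tsv(path, markers: MarkerTable, sigma_path=None) -> dict:
    df = pd.read_csv(path, sep="\t")
    sigmas = {}
    if sigma_path is not None:
        sdf = pd.read_csv(sigma_path, sep="\t")
        sigmas = dict(zip(sdf["trait"], sdf["sigma_a"]))
    id_pos = {m: i for i, m in enumerate(markers.ids)}
    out = {}
    for trait, g in df.groupby("trait", sort=False):
        e = np.full(markers.n_markers, np.nan)
        # effect files commonly cover the full chip; markers dropped by QC
        # are simply ignored
        for mid, val in zip(g["marker_id"], g["effect"]):
            if mid in id_pos:
                e[id_pos[mid]] = val
        if np.isnan(e).any():
            raise ValueError(f"trait {trait!r} is missing effects for some markers")
        out[trait] = SNPEffectSet(str(trait), e, sigmas.get(trait))
    return out


def write_segments_tsv(path, segmap: SegmentMap) -> None:
    segmap.to_frame().to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> SegmentMap:
    df = pd.read_csv(path, sep="\t")
    return SegmentMap(df["chrom"].to_numpy(), df["start_snp"].to_numpy(),
                      df["end_snp"].to_numpy(), df["recomb_to_next"].to_numpy())


def write_pedigree_csv(path, ped) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path):
    from .relatedness import Pedigree

    return Pedigree.from_frame(pd.read_csv(path, dtype={"animal": str, "sire": str,
                                                        "dam": str}))


def write_gamete_stats_tsv(path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_gamete_stats_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see ``run_pipeline``)."""

    out_dir: str
    seed: int | None = None
    simulate: dict | None = None           # SimConfig-style keyword overrides
    genotypes: str | None = None           # VCF path (alternative to simulate)
    genotype_format: str = "vcf"
    markers: str | None = None             # marker TSV (hap-tsv import)
    effects: str | None = None             # effects TSV
    sigma: str | None = None
    segments: str | None = None            # segment TSV; else built
    n_segments: int | None = None
    min_call_rate: float = MIN_CALL_RATE
    min_maf: float = MIN_MAF
    gamete_n: int = 100_000
    gamete_method: str = "analytic"
    crossover_rate: float = 0.3
    crossover_law: str = "poisson"
    thresholds: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)
    gamma: float = 0.999
    mating_sires: tuple = ()
    mating_dams: tuple = ()
    inbreeding: bool = False
    freq_mode: str = "founder-mean"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run import (or simulation) -> haplotype BVs -> gamete statistics ->
    optional mating table and inbreeding, writing every artifact and a JSON
    manifest; returns the manifest."""
    from . import __version__
    from .gametes import RecombinationModel, population_gamete_scan
    from .mating import GameteStats, mate_table, mating_frame
    from .relatedness import (base_allele_frequencies, genomic_inbreeding,
                              pedigree_inbreeding, usable_snps)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "outputs": {}}
    model = RecombinationModel(config.crossover_rate, config.crossover_law)

    def stage(name):
        manifest["stages"].append(name)

    ped = None
    truth = None
    if config.simulate is not None:
        if config.seed is None:
            raise ValueError("a seed is required when simulation is requested")
        from .simulate import SimConfig, TraitSpec, simulate_population

        stage("simulate")
        sim_kwargs = dict(config.simulate)
        traits = sim_kwargs.pop("traits", None)
        if traits is not None:
            sim_kwargs["traits"] = tuple(TraitSpec(**t) for t in traits)
        pop = simulate_population(SimConfig(**sim_kwargs), config.seed)
        markers, phased, segmap = pop.markers, pop.phased, pop.segmap
        effect_sets, ped, truth = pop.effects, pop.pedigree, pop.truth
        write_vcf(out / "genotypes.vcf", markers, phased)
        write_markers_tsv(out / "markers.tsv", markers)
        write_effects_tsv(out / "effects.tsv", effect_sets, markers,
                          out / "sigma.tsv")
        write_pedigree_csv(out / "pedigree.csv", ped)
        write_truth_tsv(out / "truth.tsv", truth)
        manifest["outputs"]["genotypes"] = str(out / "genotypes.vcf")
        qc = QCReport(n_animals_in=phased.n_animals, n_animals_kept=phased.n_animals,
                      n_snps_in=markers.n_markers, n_snps_kept=markers.n_markers)
    else:
        if config.genotypes is None or config.effects is None:
            raise ValueError("either 'simulate' or genotype+effect inputs are required")
        stage("import")
        ext_markers = read_markers_tsv(config.markers) if config.markers else None
        phased, markers, qc = import_genotypes(
            config.genotypes, config.genotype_format, ext_markers,
            config.min_call_rate, config.min_maf)
        effect_sets = read_effects_tsv(config.effects, markers, config.sigma)
        if config.segments:
            segmap = read_segments_tsv(config.segments)
        else:
            n_seg = config.n_segments or 2 * len(markers.chromosomes)
            segmap = build_segment_map(markers, n_seg,
                                       crossover_rate=config.crossover_rate)
    manifest["qc"] = qc.to_dict()
    write_segments_tsv(out / "segments.tsv", segmap)
    manifest["outputs"]["segments"] = str(out / "segments.tsv")

    stage("haplotype-bv")
    stage("gamete-stats")
    if config.gamete_method == "monte-carlo" and config.seed is None:
        raise ValueError("a seed is required for Monte-Carlo gamete statistics")
    frames = []
    for trait, eff in effect_sets.items():
        hapbv = haplotype_breeding_values(phased, eff, segmap)
        frames.append(population_gamete_scan(
            hapbv, segmap, model, config.gamete_n, config.seed,
            config.gamete_method))
    stats = pd.concat(frames, ignore_index=True)
    write_gamete_stats_tsv(out / "gamete_stats.tsv", stats)
    manifest["outputs"]["gamete_stats"] = str(out / "gamete_stats.tsv")

    if config.mating_sires and config.mating_dams:
        stage("mating")
        results = []
        for trait in effect_sets:
            sub = stats[stats.trait == trait].set_index("animal_id")

            def gs(a):
                return GameteStats(a, trait, float(sub.loc[a, "mgbv"]),
                                   float(sub.loc[a, "sdgbv"]),
                                   int(sub.loc[a, "n_replicates"]))

            for s in config.mating_sires:
                for d in config.mating_dams:
                    results.append(mate_table(gs(s), gs(d), config.thresholds,
                                              config.gamma))
        mating_frame(results).to_csv(out / "matings.tsv", sep="\t", index=False)
        manifest["outputs"]["matings"] = str(out / "matings.tsv")

    if config.inbreeding:
        if ped is None:
            raise ValueError("inbreeding requires a pedigree (simulate mode)")
        stage("inbreeding")
        fp = pedigree_inbreeding(ped)
        dos = phased.dosages()
        p = base_allele_frequencies(dos, phased.animal_ids, ped, config.freq_mode)
        ok = usable_snps(p)
        fg = genomic_inbreeding(dos[:, ok], p[ok])
        pd.DataFrame({"animal": phased.animal_ids, "f_g": fg,
                      "f_p": [fp[ped.index_of(a)] for a in phased.animal_ids]}
                     ).to_csv(out / "inbreeding.tsv", sep="\t", index=False)
        manifest["outputs"]["inbreeding"] = str(out / "inbreeding.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
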