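"""Validation of predicted gametic variation against realized progeny data.

The prediction is checked by reconstructing, for each offspring, the
haplotype transmitted by a chosen parent, scoring it with half the SNP
effects (a transmitted-haplotype breeding value), and comparing the
within-progeny-group SD of those values with the parent's predicted SDGBV
across sires.  Trend reporting summarizes gamete statistics by birth year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .haplotypes import (MATERNAL, PATERNAL, UNKNOWN, PhasedGenotypes,
                         SegmentMap, SNPEffectSet)


def transmitted_haplotype_bv(
    phased: PhasedGenotypes,
    effects: SNPEffectSet,
    parent_role: str = PATERNAL,
) -> np.ndarray:
    """Genome-wide breeding value of the haplotype each animal received
    from the designated parent: sum_k z_k * (effect_k / 2) over that
    origin's phase."""
    if parent_role not in (PATERNAL, MATERNAL):
        raise ValueError(f"parent_role must be paternal or maternal, got {parent_role!r}")
    if phased.n_markers != len(effects.effects):
        raise ValueError("effects length does not match marker count")
    slots = np.empty(phased.n_animals, dtype=np.int64)
    for a in range(phased.n_animals):
        match = np.flatnonzero(phased.origin[a] == parent_role)
        if match.size != 1:
            raise ValueError(
                f"animal {phased.animal_ids[a]!r} has no resolved {parent_role} "
                "phase; run assign_parental_origin first")
        slots[a] = match[0]
    alpha = effects.effects / 2.0
    picked = phased.alleles[np.arange(phased.n_animals), :, slots]
    return picked @ alpha


def assign_parental_origin(
    offspring: PhasedGenotypes,
    sire: PhasedGenotypes,
    segmap: SegmentMap,
    dam: PhasedGenotypes | None = None,
) -> tuple[PhasedGenotypes, np.ndarray]:
    """Label offspring phases by parental origin via segment-wise matching
    against the sire's two haplotypes.

    Per segment, the offspring phase with the higher best-match rate to
    either sire haplotype is called paternal (majority vote over the
    segment's SNPs; the dam's haplotypes break ties when given).  An
    unresolved segment inherits the previous segment's call; leading ties
    stay unknown, and an animal with any unknown segment keeps unknown
    origin labels.

    Returns a new PhasedGenotypes with alleles reordered so slot 0 is the
    paternal haplotype wherever resolved, plus the per-segment label matrix
    (0/1 = offspring slot called paternal, -1 = unknown).
    """
    if offspring.n_markers != sire.n_markers or segmap.n_snps != offspring.n_markers:
        raise ValueError("offspring, sire and segment map must share the marker set")
    if sire.n_animals != 1 and sire.n_animals != offspring.n_animals:
        raise ValueError("sire set must hold one animal or one per offspring")
    S = segmap.n_segments
    labels = np.full((offspring.n_animals, S), -1, dtype=np.int64)
    out = offspring.alleles.copy()
    origin = np.full((offspring.n_animals, 2), UNKNOWN, dtype=object)

    for a in range(offspring.n_animals):
        sh = sire.alleles[0 if sire.n_animals == 1 else a]
        dh = None if dam is None else dam.alleles[0 if dam.n_animals == 1 else a]
        prev = -1
        for s in range(S):
            sl = slice(segmap.start[s], segmap.end[s])
            off = offspring.alleles[a, sl]  # (snps, 2)
            score = np.empty(2)
            for j in (0, 1):
                score[j] = max((off[:, j] == sh[sl, 0]).mean(),
                               (off[:, j] == sh[sl, 1]).mean())
            if score[0] != score[1]:
                lab = int(np.argmax(score))
            elif dh is not None:
                dscore = np.empty(2)
                for j in (0, 1):
                    # the *other* phase should match the dam
                    dscore[j] = max((off[:, 1 - j] == dh[sl, 0]).mean(),
                                    (off[:, 1 - j] == dh[sl, 1]).mean())
                lab = int(np.argmax(dscore)) if dscore[0] != dscore[1] else prev
            else:
                lab = prev
            labels[a, s] = lab
            prev = lab
        # back-fill leading carries that resolved later? leading ties stay
        # unknown by contract; only forward inheritance is applied above.
        if np.all(labels[a] >= 0):
            for s in range(S):
                if labels[a, s] == 1:
                    sl = slice(segmap.start[s], segmap.end[s])
                    out[a, sl] = out[a, sl][:, ::-1]
            origin[a] = [PATERNAL, MATERNAL]
    labeled = PhasedGenotypes(list(offspring.animal_ids), out, origin)
    return labeled, labels


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def progeny_group_validation(
    predicted_sdgbv: dict[str, float],
    transmitted_by_sire: dict[str, np.ndarray],
    min_offspring_grid=(10, 50, 100, 150, 200, 300, 500),
) -> pd.DataFrame:
    """Correlation between predicted SDGBV and the observed SD of
    transmitted-haplotype values per sire, by minimum progeny-group size.

    Returns one row per grid value: min_offspring, n_sires, r (NaN when
    fewer than two sires qualify).
    """
    rows = []
    for cutoff in min_offspring_grid:
        # an observed SD needs at least two offspring regardless of the grid
        sires = [s for s, v in transmitted_by_sire.items()
                 if len(v) >= max(cutoff, 2) and s in predicted_sdgbv]
        obs = np.array([np.std(transmitted_by_sire[s], ddof=1) for s in sires])
        pred = np.array([predicted_sdgbv[s] for s in sires])
        rows.append({"min_offspring": int(cutoff), "n_sires": len(sires),
                     "r": pearson_r(pred, obs) if len(sires) >= 2 else float("nan")})
    return pd.DataFrame(rows)


def trend_report(
    stats: pd.DataFrame,
    ped,
    transmitted: pd.DataFrame | None = None,
) -> dict:
    """Per-birth-year means and OLS slopes of gamete statistics.

    ``stats`` is a population_gamete_scan frame; birth years come from the
    pedigree.  ``transmitted`` (optional) carries per-offspring columns
    animal_id, trait, paternal, maternal for the parental-path trends.
    Returns {"yearly": DataFrame, "slopes": DataFrame} with one slope (SDGBV
    per year) per trait, NaN when only one birth year is present.
    """
    year = {a: int(y) for a, y in zip(ped.ids, ped.birth_year)}
    df = stats.copy()
    df["birth_year"] = df["animal_id"].map(year)
    if df["birth_year"].isna().any():
        raise ValueError("stats contain animals missing from the pedigree")
    yearly = (df.groupby(["trait", "birth_year"])
                .agg(mean_mgbv=("mgbv", "mean"), mean_sdgbv=("sdgbv", "mean"),
                     n=("animal_id", "size"))
                .reset_index())
    if transmitted is not None:
        t = transmitted.copy()
        t["birth_year"] = t["animal_id"].map(year)
        tp = (t.groupby(["trait", "birth_year"])
                .agg(mean_paternal=("paternal", "mean"),
                     mean_maternal=("maternal", "mean"))
                .reset_index())
        yearly = yearly.merge(tp, on=["trait", "birth_year"], how="left")
    slopes = []
    for trait, g in df.groupby("trait"):
        yrs = g["birth_year"].to_numpy(dtype=float)
        if np.unique(yrs).size < 2:
            slope = float("nan")
        else:
            slope = float(np.polyfit(yrs, g["sdgbv"].to_numpy(), 1)[0])
        slopes.append({"trait": trait, "sdgbv_slope_per_year": slope})
    return {"yearly": yearly, "slopes": pd.DataFrame(slopes)}


def normal_quantile_table(values: np.ndarray, probs=(0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)) -> pd.DataFrame:
    """Observed vs fitted-normal quantiles (numeric stand-in for a Q-Q
    inspection of MGBV/SDGBV distributions)."""
    from scipy.stats import norm

    v = np.asarray(values, dtype=np.float64)
    mu, sd = v.mean(), v.std(ddof=1)
    return pd.DataFrame({
        "prob": probs,
        "observed": np.quantile(v, probs),
        "fitted_normal": norm.ppf(probs, loc=mu, scale=sd),
    })
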