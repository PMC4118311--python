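"""Mating-plan statistics built on parental gamete moments.

Offspring breeding values of a sire x dam mating are modelled as normal
with mean mBV = MGBV_s + MGBV_d and standard deviation
sBV = sqrt(SDGBV_s^2 + SDGBV_d^2) (no sire-dam covariance).  From that
distribution the planner derives threshold-exceedance probabilities and,
via the binomial at-least-one-success formula, the number of matings
needed to reach a target offspring with a chosen confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .gametes import GameteStats


@dataclass
class MatingResult:
    """Offspring distribution and decision numbers for one sire x dam pair."""

    sire_id: str
    dam_id: str
    trait: str
    mbv: float
    sbv: float
    thresholds: tuple = ()
    probabilities: tuple = ()  # fractions, aligned with thresholds
    matings_needed: tuple = ()  # int or None (impossible), aligned
    gamma: float = 0.999


def mate(sire: GameteStats, dam: GameteStats) -> tuple[float, float]:
    """Expected offspring mean and SD: (mBV, sBV)."""
    if sire.trait != dam.trait:
        raise ValueError(f"trait mismatch: {sire.trait!r} vs {dam.trait!r}")
    mbv = sire.mgbv + dam.mgbv
    sbv = math.hypot(sire.sdgbv, dam.sdgbv)
    return mbv, sbv


def prob_exceed(mbv: float, sbv: float, threshold: float) -> float:
    """P(offspring breeding value > threshold) under the normal model."""
    if sbv < 0:
        raise ValueError("sBV must be non-negative")
    if sbv == 0:
        return 1.0 if mbv > threshold else 0.0
    return float(norm.sf((threshold - mbv) / sbv))


def required_matings(
    p: float, gamma: float = 0.999, rounding: str = "nearest"
) -> int | None:
    """Matings needed so that P(at least one success) >= gamma, success
    probability ``p`` per mating: n* = ln(1-gamma)/ln(1-p).

    Returns None when the event is impossible (p = 0); always >= 1.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        return None
    if p == 1:
        return 1
    n = math.log1p(-gamma) / math.log1p(-p)
    if rounding == "nearest":
        k = round(n)
    elif rounding == "ceiling":
        k = math.ceil(n)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return max(1, int(k))


def mate_table(
    sire: GameteStats,
    dam: GameteStats,
    thresholds=(0.0, 1.0, 2.0, 3.0, 4.0),
    gamma: float = 0.999,
    rounding: str = "nearest",
) -> MatingResult:
    """Full decision row for one mating: mBV, sBV, p and N per threshold."""
    mbv, sbv = mate(sire, dam)
    probs = tuple(prob_exceed(mbv, sbv, t) for t in thresholds)
    ns = tuple(required_matings(p, gamma, rounding) for p in probs)
    return MatingResult(sire.animal_id, dam.animal_id, sire.trait,
                        mbv, sbv, tuple(thresholds), probs, ns, gamma)


def format_percent(p: float) -> str:
    """Percentage with one decimal; >= 99.95% renders as '100'."""
    pct = 100.0 * p
    return "100" if pct >= 99.95 else f"{pct:.1f}"


def plan_matings(
    portfolio: list[GameteStats],
    cows: list[GameteStats],
    threshold: float,
    min_probability: float = 0.0,
    pedigree=None,
    bull_filter=None,
    gamma: float = 0.999,
) -> dict[str, list[MatingResult]]:
    """Ranked bull list per cow: bulls whose offspring exceed ``threshold``
    with probability >= ``min_probability``, sorted by that probability
    (ties: higher mBV, then bull id).

    ``pedigree`` (a relatedness.Pedigree) excludes a cow's own sire and her
    offspring from her list; ``bull_filter(bull_id, cow_id) -> bool`` hooks
    in ownership constraints.
    """
    if not portfolio:
        warnings.warn("empty bull portfolio; no matings proposed")
        return {c.animal_id: [] for c in cows}
    sire_of, offspring_of = {}, {}
    if pedigree is not None:
        for i, a in enumerate(pedigree.ids):
            s = pedigree.sire[i]
            if s >= 0:
                sire_of[a] = pedigree.ids[s]
                offspring_of.setdefault(pedigree.ids[s], set()).add(a)
    plans: dict[str, list[MatingResult]] = {}
    for cow in cows:
        rows = []
        for bull in portfolio:
            if bull_filter is not None and not bull_filter(bull.animal_id, cow.animal_id):
                continue
            if sire_of.get(cow.animal_id) == bull.animal_id:
                continue
            if bull.animal_id in offspring_of.get(cow.animal_id, ()):
                continue
            res = mate_table(bull, cow, (threshold,), gamma)
            if res.probabilities[0] >= min_probability:
                rows.append(res)
        rows.sort(key=lambda r: (-r.probabilities[0], -r.mbv, r.sire_id))
        plans[cow.animal_id] = rows
    return plans


def mating_frame(results: list[MatingResult]) -> pd.DataFrame:
    """Tabular (file-ready) form of mating results; probabilities as
    percentages with one decimal, impossible N rendered '-'."""
    rows = []
    for r in results:
        row = {"sire": r.sire_id, "dam": r.dam_id, "trait": r.trait,
               "mbv": round(r.mbv, 2), "sbv": round(r.sbv, 2)}
        for t, p in zip(r.thresholds, r.probabilities):
            row[f"p_at_{t:g}"] = format_percent(p)
        for t, p, n in zip(r.thresholds, r.probabilities, r.matings_needed):
            # events whose probability prints as 0 render an undefined N
            row[f"n_at_{t:g}"] = "-" if n is None or p < 0.0005 else str(n)
        rows.append(row)
    return pd.DataFrame(rows)
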