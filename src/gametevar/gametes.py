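"""Monte-Carlo gamete simulation and exact moments of gamete breeding values.

A parent transmits, per chromosome, a mosaic of its two phased haplotypes:
the starting phase is a fair coin, the number of crossovers per chromosome
follows the configured law (Poisson with mean 0.3 by default), and each
crossover lands on a uniformly chosen segment junction, flipping the phase
there.  The gamete breeding value is the sum over segments of the selected
phase's haplotype breeding value h.

MGBV is the mean and SDGBV the (N-1)-denominator standard deviation of the
simulated gamete values; `analytic_gamete_moments` gives both moments in
closed form, without sampling, for the identical crossover process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeBVTable, SegmentMap, poisson_junction_prob

POISSON = "poisson"
BERNOULLI = "bernoulli-at-most-one"
MAP = "map"


@dataclass
class RecombinationModel:
    """Crossover process per chromosome per meiosis.

    rate
        Expected crossovers per chromosome (default 0.3).
    law
        "poisson": crossover count ~ Poisson(rate);
        "bernoulli-at-most-one": one crossover with probability `rate`;
        "map": independent per-junction flips with the probabilities stored
        in the segment map (`recomb_to_next`), ignoring `rate`.
    """

    rate: float = 0.3
    law: str = POISSON

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("crossover rate must be non-negative")
        if self.law not in (POISSON, BERNOULLI, MAP):
            raise ValueError(f"unknown crossover law: {self.law!r}")
        if self.law == BERNOULLI and self.rate > 1:
            raise ValueError("bernoulli-at-most-one requires rate <= 1")


@dataclass
class GameteStats:
    """Gamete breeding-value moments for one parent and trait.

    ``n`` is the number of Monte-Carlo replicates (0 for the analytic
    method); units follow the haplotype table (sigma_a when effects were
    scaled)."""

    animal_id: str
    trait: str
    mgbv: float
    sdgbv: float
    n: int
    method: str = "monte-carlo"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sdgbv < 0:
            raise ValueError("SDGBV must be non-negative")


def junction_probs(segmap: SegmentMap, model: RecombinationModel) -> np.ndarray:
    """Marginal phase-flip probability at each junction (length n_segments;
    entry s refers to the junction after segment s, 0 at chromosome ends)."""
    r = np.zeros(segmap.n_segments)
    for _, sl in segmap.chromosome_slices():
        J = sl.stop - sl.start - 1
        if J == 0:
            continue
        if model.law == POISSON:
            r[sl.start:sl.stop - 1] = poisson_junction_prob(model.rate, J)
        elif model.law == BERNOULLI:
            r[sl.start:sl.stop - 1] = model.rate / J
        else:
            r[sl.start:sl.stop - 1] = segmap.recomb_to_next[sl.start:sl.stop - 1]
    return r


def _sample_phase_matrix(
    rng: np.random.Generator, segmap: SegmentMap, model: RecombinationModel, n: int
) -> np.ndarray:
    """(n, n_segments) matrix of selected phase slots (0/1) for n gametes."""
    phases = np.empty((n, segmap.n_segments), dtype=np.int8)
    for _, sl in segmap.chromosome_slices():
        S = sl.stop - sl.start
        J = S - 1
        start = rng.integers(0, 2, size=n, dtype=np.int8)
        if J == 0:
            phases[:, sl.start] = start
            continue
        if model.law == POISSON:
            # Poisson splitting: per-junction counts ~ Poisson(rate/J); the
            # junction flips iff its count is odd — exactly the same law as
            # drawing the total count then placing each crossover uniformly.
            flips = (rng.poisson(model.rate / J, size=(n, J)) & 1).astype(np.int8)
        elif model.law == BERNOULLI:
            occurs = rng.random(n) < model.rate
            where = rng.integers(0, J, size=n)
            flips = np.zeros((n, J), dtype=np.int8)
            flips[occurs, where[occurs]] = 1
        else:
            r = segmap.recomb_to_next[sl.start:sl.stop - 1]
            flips = (rng.random((n, J)) < r[None, :]).astype(np.int8)
        cum = np.cumsum(flips, axis=1, dtype=np.int32)
        phases[:, sl.start] = start
        phases[:, sl.start + 1:sl.stop] = (start[:, None] + cum) & 1
    return phases


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required")
    return np.random.default_rng(seed)


def sample_gametes(
    hapbv_row: np.ndarray,
    segmap: SegmentMap,
    model: RecombinationModel,
    n: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``n`` gamete breeding values for one parent.

    ``hapbv_row`` is the (n_segments, 2) slice of a HaplotypeBVTable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h = np.asarray(hapbv_row, dtype=np.float64)
    if h.shape != (segmap.n_segments, 2):
        raise ValueError("hapbv_row must have shape (n_segments, 2)")
    rng = _as_rng(seed)
    m = 0.5 * (h[:, 0] + h[:, 1])
    d = 0.5 * (h[:, 0] - h[:, 1])
    phases = _sample_phase_matrix(rng, segmap, model, n)
    signs = 1.0 - 2.0 * phases  # +1 selects phase slot 0
    return m.sum() + signs @ d


def gamete_stats(
    sample: np.ndarray,
    animal_id: str = "",
    trait: str = "",
    seed: int | None = None,
) -> GameteStats:
    """MGBV (mean) and SDGBV (sample SD, N-1 denominator) of gamete values."""
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size < 2:
        raise ValueError("at least two replicates are required for SDGBV")
    return GameteStats(animal_id, trait, float(sample.mean()),
                       float(sample.std(ddof=1)), int(sample.size),
                       "monte-carlo", seed)


def analytic_gamete_moments(
    hapbv_row: np.ndarray,
    segmap: SegmentMap,
    model: RecombinationModel,
    animal_id: str = "",
    trait: str = "",
) -> GameteStats:
    """Exact MGBV and SDGBV for the crossover process, without sampling.

    With m_s = (h_pat + h_mat)/2 and d_s = (h_pat - h_mat)/2,
    MGBV = sum m_s and Var = sum d_s^2 + 2 sum_{s<t, same chrom}
    d_s d_t rho_{s,t}, where rho is the phase-agreement correlation: for
    independent junction flips (poisson/map laws) the product of (1 - 2r)
    over the junctions in between; for the at-most-one-crossover law
    1 - 2*rate*k/J with k junctions in between.
    """
    h = np.asarray(hapbv_row, dtype=np.float64)
    if h.shape != (segmap.n_segments, 2):
        raise ValueError("hapbv_row must have shape (n_segments, 2)")
    m = 0.5 * (h[:, 0] + h[:, 1])
    d = 0.5 * (h[:, 0] - h[:, 1])
    r = junction_probs(segmap, model)
    var = float(np.dot(d, d))
    for _, sl in segmap.chromosome_slices():
        dc = d[sl]
        S = len(dc)
        if S < 2:
            continue
        if model.law == BERNOULLI:
            J = S - 1
            for s in range(S - 1):
                k = np.arange(1, S - s)
                rho = 1.0 - 2.0 * model.rate * k / J
                var += 2.0 * dc[s] * float(np.dot(dc[s + 1:], rho))
        else:
            decay = 1.0 - 2.0 * r[sl][:-1]  # junction after segment s
            # c[t] = sum_{s<t} d_s * prod_{j=s..t-1}(1-2 r_j), by recursion
            c = 0.0
            acc = 0.0
            for t in range(1, S):
                c = (c + dc[t - 1]) * decay[t - 1]
                acc += dc[t] * c
            var += 2.0 * acc
    var = max(var, 0.0)
    return GameteStats(animal_id, trait, float(m.sum()), float(np.sqrt(var)),
                       0, "analytic", None)


def population_gamete_scan(
    hapbv: HaplotypeBVTable,
    segmap: SegmentMap,
    model: RecombinationModel | None = None,
    n: int = 100_000,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> pd.DataFrame:
    """GameteStats for every animal in a haplotype table, as a DataFrame.

    Monte-Carlo sub-streams are spawned deterministically from the master
    seed and the animal index, so the scan is reproducible and each animal's
    stream is independent.
    """
    model = model or RecombinationModel()
    rows = []
    for i, animal in enumerate(hapbv.animal_ids):
        row = hapbv.values[i]
        if method == "analytic":
            st = analytic_gamete_moments(row, segmap, model, animal, hapbv.trait)
        elif method == "monte-carlo":
            if seed is None:
                raise ValueError("monte-carlo scan requires a seed")
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
            st = gamete_stats(sample_gametes(row, segmap, model, n, rng),
                              animal, hapbv.trait, seed)
        else:
            raise ValueError(f"unknown method: {method!r}")
        rows.append({"animal_id": st.animal_id, "trait": st.trait,
                     "mgbv": st.mgbv, "sdgbv": st.sdgbv, "n_replicates": st.n,
                     "method": st.method, "seed": seed})
    return pd.DataFrame(rows)
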