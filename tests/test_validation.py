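import numpy as np
import pandas as pd
import pytest

from gametevar import (PhasedGenotypes, RecombinationModel, SimConfig,
                       SNPEffectSet, TraitSpec, analytic_gamete_moments,
                       assign_parental_origin, haplotype_breeding_values,
                       progeny_group_validation, simulate_population,
                       transmitted_haplotype_bv, trend_report)
from gametevar.validation import normal_quantile_table, pearson_r

from oracles import two_pass_pearson


@pytest.fixture(scope="module")
def trio_pop():
    cfg = SimConfig(n_founders=4, n_generations=1, offspring_per_generation=8,
                    n_chromosomes=3, snps_per_chromosome=20,
                    segments_per_chromosome=3,
                    traits=(TraitSpec("protein", reliability=1.0),))
    return simulate_population(cfg, seed=101)


class TestTransmittedHaplotypeBV:
    def test_equals_truth_recorded_gamete_value(self, trio_pop):
        pop = trio_pop
        off_ids = [a for a in pop.phased.animal_ids if a.startswith("G1")]
        off = pop.phased.subset(off_ids)
        vals = transmitted_haplotype_bv(off, pop.effects["protein"], "paternal")
        truth = pop.truth[pop.truth.role == "paternal"].set_index("offspring")
        expected = [truth.loc[a, "gamete_bv_protein"] for a in off_ids]
        assert np.allclose(vals, expected)

    def test_zero_effects_give_zero(self, trio_pop):
        pop = trio_pop
        off = pop.phased.subset([a for a in pop.phased.animal_ids
                                 if a.startswith("G1")])
        zero = SNPEffectSet("protein", np.zeros(pop.markers.n_markers))
        assert np.all(transmitted_haplotype_bv(off, zero) == 0)

    def test_unknown_origin_rejected(self, trio_pop):
        pop = trio_pop
        founders = pop.phased.subset(["G0_0000"])  # founder origin unknown
        with pytest.raises(ValueError, match="assign_parental_origin"):
            transmitted_haplotype_bv(founders, pop.effects["protein"])


class TestAssignParentalOrigin:
    def test_recovers_simulator_transmission(self, trio_pop):
        pop = trio_pop
        ped = pop.pedigree
        off_ids = [a for a in pop.phased.animal_ids if a.startswith("G1")]
        rng = np.random.default_rng(6)
        truth = pop.truth[pop.truth.role == "paternal"].set_index("offspring")
        for oid in off_ids:
            sid = pop.phased.animal_ids[ped.sire[ped.index_of(oid)]]
            off = pop.phased.subset([oid])
            # scramble the phase order to discard origin labels
            alleles = off.alleles.copy()
            if rng.random() < 0.5:
                alleles = alleles[:, :, ::-1]
            unlabeled = PhasedGenotypes([oid], alleles)
            labeled, _ = assign_parental_origin(
                unlabeled, pop.phased.subset([sid]), pop.segmap)
            v = transmitted_haplotype_bv(labeled, pop.effects["protein"])
            assert v[0] == pytest.approx(truth.loc[oid, "gamete_bv_protein"])

    def test_offspring_identical_to_one_sire_haplotype(self, trio_pop):
        pop = trio_pop
        sire = pop.phased.subset(["G0_0000"])
        alleles = np.empty((1, pop.markers.n_markers, 2), dtype=np.uint8)
        alleles[0, :, 0] = sire.alleles[0, :, 1]  # transmitted intact
        alleles[0, :, 1] = 1 - sire.alleles[0, :, 1]
        off = PhasedGenotypes(["kid"], alleles)
        labeled, labels = assign_parental_origin(off, sire, pop.segmap)
        assert np.all(labels == 0)
        assert np.array_equal(labeled.alleles[0, :, 0], sire.alleles[0, :, 1])

    def test_uninformative_trio_stays_unknown(self, trio_pop):
        pop = trio_pop
        M = pop.markers.n_markers
        hom = np.zeros((1, M, 2), dtype=np.uint8)
        sire = PhasedGenotypes(["s"], hom)
        off = PhasedGenotypes(["o"], hom)
        labeled, labels = assign_parental_origin(off, sire, pop.segmap)
        assert np.all(labels == -1)
        assert np.all(labeled.origin == "unknown")


class TestProgenyGroupValidation:
    def test_perfect_predictions_give_r_one(self, rng):
        groups = {f"s{i}": rng.normal(0, 0.1 * (i + 1), size=50)
                  for i in range(6)}
        pred = {s: np.std(v, ddof=1) for s, v in groups.items()}
        out = progeny_group_validation(pred, groups, (10,))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "n_sires"] == 6

    def test_cutoff_above_group_sizes_undefined(self, rng):
        groups = {"s0": rng.normal(size=20), "s1": rng.normal(size=30)}
        pred = {"s0": 1.0, "s1": 1.1}
        out = progeny_group_validation(pred, groups, (10, 25, 100))
        assert out["n_sires"].tolist() == [2, 1, 0]
        assert np.isnan(out.loc[1, "r"]) and np.isnan(out.loc[2, "r"])

    def test_sire_counts_non_increasing_with_cutoff(self, rng):
        groups = {f"s{i}": rng.normal(size=rng.integers(5, 200))
                  for i in range(20)}
        pred = {s: 1.0 + 0.01 * i for i, s in enumerate(groups)}
        out = progeny_group_validation(pred, groups, (10, 50, 100))
        assert (np.diff(out["n_sires"]) <= 0).all()

    def test_pearson_matches_two_pass_oracle(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson_r(x, y) == pytest.approx(two_pass_pearson(x, y))


class TestProgenyMomentConvergence:
    def test_group_mean_and_sd_converge_to_prediction(self):
        # many simulated meioses of one parent reproduce its analytic
        # MGBV within 4 SE and SDGBV within 5%
        from gametevar import sample_gametes
        from gametevar.simulate import _meiosis

        cfg = SimConfig(n_founders=2, n_generations=0, n_chromosomes=5,
                        snps_per_chromosome=30,
                        traits=(TraitSpec("t", reliability=1.0),))
        pop = simulate_population(cfg, seed=5)
        hap = haplotype_breeding_values(pop.phased, pop.effects["t"], pop.segmap)
        model = cfg.recombination
        pred = analytic_gamete_moments(hap.values[0], pop.segmap, model)
        rng = np.random.default_rng(9)
        snp_seg = pop.segmap.snp_to_segment()
        alpha = pop.effects["t"].effects / 2.0
        n = 10_000
        vals = np.empty(n)
        for i in range(n):
            gam, _ = _meiosis(rng, pop.phased.alleles[0], pop.segmap, model, snp_seg)
            vals[i] = gam @ alpha
        assert vals.mean() == pytest.approx(pred.mgbv, abs=4 * pred.sdgbv / np.sqrt(n))
        assert vals.std(ddof=1) == pytest.approx(pred.sdgbv, rel=0.05)


class TestTrendReport:
    def test_constant_sdgbv_slope_zero(self):
        from gametevar import Pedigree

        ped = Pedigree(["a", "b", "c"], np.full(3, -1), np.full(3, -1),
                       birth_year=np.array([2000, 2001, 2002]))
        stats = pd.DataFrame({"animal_id": ["a", "b", "c"], "trait": "t",
                              "mgbv": [0.1, 0.2, 0.3], "sdgbv": [0.4, 0.4, 0.4]})
        rep = trend_report(stats, ped)
        assert rep["slopes"].loc[0, "sdgbv_slope_per_year"] == pytest.approx(0.0)
        assert rep["yearly"].shape[0] == 3

    def test_single_birth_year_slope_undefined(self):
        from gametevar import Pedigree

        ped = Pedigree(["a", "b"], np.full(2, -1), np.full(2, -1),
                       birth_year=np.array([2000, 2000]))
        stats = pd.DataFrame({"animal_id": ["a", "b"], "trait": "t",
                              "mgbv": [0.0, 0.1], "sdgbv": [0.3, 0.5]})
        rep = trend_report(stats, ped)
        assert np.isnan(rep["slopes"].loc[0, "sdgbv_slope_per_year"])

    def test_sire_selection_lifts_paternal_path(self):
        # directional selection on sires only: the paternally inherited
        # haplotype values trend above the maternally inherited ones
        cfg = SimConfig(n_founders=120, n_generations=3,
                        offspring_per_generation=120, n_chromosomes=5,
                        snps_per_chromosome=30, selection="sires-only",
                        sire_fraction=0.1,
                        traits=(TraitSpec("t", reliability=1.0),))
        pop = simulate_population(cfg, seed=21)
        t = pop.truth
        pat = t[t.role == "paternal"]["gamete_bv_t"].mean()
        mat = t[t.role == "maternal"]["gamete_bv_t"].mean()
        assert pat > mat


def test_normal_quantile_table_shapes(rng):
    tab = normal_quantile_table(rng.normal(size=500))
    assert list(tab.columns) == ["prob", "observed", "fitted_normal"]
    mid = tab[tab.prob == 0.5]
    assert abs(mid["observed"].iloc[0] - mid["fitted_normal"].iloc[0]) < 0.2
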