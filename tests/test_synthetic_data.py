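"""Simulator unit and property tests: founders, breeding, assays, pools."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from matescan import quantgen
from matescan import synthetic_data as sd
from matescan.datatypes import InversionBlock, Population, TraitModel


class TestFounders:
    def test_inbred_dosage_coding(self):
        panel = sd.simulate_founders(40, 1000, seed=1)
        assert panel.genotypes.dosage.shape == (40, 1000)
        assert set(np.unique(panel.genotypes.dosage)) <= {0.0, 2.0}

    def test_wolbachia_rate_zero_means_uninfected(self):
        panel = sd.simulate_founders(10, 50, wolbachia_rate=0.0, seed=2)
        assert not panel.wolbachia.any()

    def test_maf_law_sample_mean(self):
        # uniform(0.05, 0.5) has mean 0.275, sd 0.45/sqrt(12)
        panel = sd.simulate_founders(40, 5000, maf_law=("uniform", 0.05, 0.5), seed=3)
        af = panel.genotypes.variants["af"].to_numpy()
        se = (0.45 / np.sqrt(12)) / np.sqrt(5000)
        assert abs(af.mean() - 0.275) < 3 * se

    def test_inversion_block_ld_with_karyotype(self, small_panel):
        block = small_panel.inversion_blocks["In(3R)K"]
        v = small_panel.genotypes.variants
        in_block = (
            (v["chrom"] == block.chrom) & (v["pos"] >= block.start) & (v["pos"] <= block.end)
        ).to_numpy()
        assert in_block.any()
        karyo = small_panel.karyotypes["In(3R)K"]
        inv_count = karyo.map({"ST/ST": 0, "ST/INV": 1, "INV/INV": 2}).to_numpy()
        if len(set(inv_count)) < 2:
            pytest.skip("panel draw produced a single karyotype class")
        block_dos = small_panel.genotypes.dosage[:, in_block].mean(axis=1)
        r = np.corrcoef(inv_count, block_dos)[0, 1]
        assert r > 0.3  # block content tracks arrangement

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            sd.simulate_founders(1, 10)
        with pytest.raises(ValueError):
            sd.simulate_founders(5, 0)
        with pytest.raises(ValueError):
            sd.simulate_founders(5, 10, maf_law=("uniform", 0.0, 0.6))
        with pytest.raises(ValueError):
            sd.simulate_founders(5, 10, maf_law=("fixed", 1.5))

    def test_determinism(self):
        a = sd.simulate_founders(8, 40, seed=9)
        b = sd.simulate_founders(8, 40, seed=9)
        np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
        pd.testing.assert_frame_equal(a.genotypes.variants, b.genotypes.variants)


class TestBreeding:
    def test_round_robin_f1_genotypes(self, forty_line_panel):
        pop = sd.build_aip(forty_line_panel, generations=1, seed=4)
        assert pop.n_individuals == 40
        # F1 genotype i carries founder haplotypes (i, i+1 mod 40) intact
        for i in (0, 17, 39):
            assert set(np.unique(pop.founder_origin[i, 0])) == {i}
            assert set(np.unique(pop.founder_origin[i, 1])) == {(i + 1) % 40}

    def test_maintenance_census_800(self, aip):
        assert aip.n_individuals == 800
        assert sd.BreedingScheme().census == 800

    def test_zero_recombination_intact_haplotypes(self, forty_line_panel):
        pop2 = sd.build_aip(forty_line_panel, generations=2, recomb_rate=0.0, seed=5)
        bounds = sd._chrom_bounds(forty_line_panel.genotypes.variants)
        for i in range(pop2.n_individuals):
            for h in (0, 1):
                for (s, e) in bounds:
                    # an intact chromosome from an F1 is constant founder origin
                    assert len(set(pop2.founder_origin[i, h, s:e])) == 1

    def test_origin_labels_partition_genome(self, aip, forty_line_panel):
        origins = aip.founder_origin
        assert origins.min() >= 0
        assert origins.max() < forty_line_panel.n_lines
        # every variant of every haplotype carries exactly one origin label
        assert origins.shape[2] == forty_line_panel.genotypes.n_variants

    def test_recombination_suppressed_in_heterokaryotypic_blocks(self, small_panel):
        # meioses of an ST/INV genotype never recombine inside the block
        block = small_panel.inversion_blocks["In(3R)K"]
        inv_state = small_panel.inv_haplotype["In(3R)K"].to_numpy()
        carriers = np.flatnonzero(inv_state == 1)
        noncarriers = np.flatnonzero(inv_state == 0)
        if len(carriers) == 0:
            pytest.skip("no inverted founder haplotype in this draw")
        L = small_panel.genotypes.n_variants
        hap_a = np.full((200, L), carriers[0], dtype=np.int16)
        hap_b = np.full((200, L), noncarriers[0], dtype=np.int16)
        rng = np.random.default_rng(6)
        gametes = sd._meiose(small_panel, hap_a, hap_b, 5e-7, rng)
        v = small_panel.genotypes.variants
        in_block = (
            (v["chrom"] == block.chrom) & (v["pos"] >= block.start) & (v["pos"] <= block.end)
        ).to_numpy()
        block_origins = gametes[:, in_block]
        # each gamete's block is inherited as a unit
        assert all(len(set(row)) == 1 for row in block_origins)

    def test_scheme_inconsistent_with_panel(self):
        panel = sd.simulate_founders(2, 10, seed=1)
        with pytest.raises(ValueError):
            sd.build_aip(panel, generations=2)


def _constant_hazard_model(h):
    return TraitModel(
        causal_idx=np.array([], dtype=int),
        effects=np.array([]),
        env_sd=0.0,
        hazard_intercept=logit(h),
        hazard_slope=0.0,
    )


def _markov_expected_proportion(h, window, n_males=10, n_females=5):
    """Exact expectation of the assay's mated proportion: Markov chain on
    the number of matings so far, binomial attempts capped by free females."""
    from scipy.stats import binom

    probs = np.zeros(n_females + 1)
    probs[0] = 1.0
    for _ in range(window):
        nxt = np.zeros_like(probs)
        for m, pm in enumerate(probs):
            if pm == 0:
                continue
            free_m, free_f = n_males - m, n_females - m
            if free_f == 0:
                nxt[m] += pm
                continue
            for a in range(free_m + 1):
                nxt[m + min(a, free_f)] += pm * binom.pmf(a, free_m, h)
        probs = nxt
    return float(np.dot(np.arange(n_females + 1), probs) / n_females)


@pytest.fixture(scope="module")
def pop(forty_line_panel):
    return sd.build_aip(forty_line_panel, generations=4, seed=21)


@pytest.fixture(scope="module")
def assay(forty_line_panel):
    pop = sd.build_aip(forty_line_panel, generations=4, seed=22)
    return sd.simulate_mating_assay(pop, _constant_hazard_model(0.02), window=120, seed=3)


class TestMatingAssay:
    def test_zero_hazard_no_matings(self, pop):
        assay = sd.simulate_mating_assay(pop, _constant_hazard_model(1e-12), window=30, seed=1)
        assert assay.vials["n_mated"].sum() == 0

    def test_saturating_hazard_all_females_mated(self, pop):
        assay = sd.simulate_mating_assay(pop, _constant_hazard_model(1 - 1e-12), window=30, seed=1)
        assert (assay.vials["n_mated"] == assay.vials["n_females"]).all()
        assert (assay.matings["latency_min"] == 1).all()

    def test_conservation_and_no_remating(self, pop):
        model = _constant_hazard_model(0.02)
        assay = sd.simulate_mating_assay(pop, model, window=60, seed=2)
        per_vial = assay.matings.groupby("vial").size()
        merged = assay.vials.set_index("vial")
        for v, cnt in per_vial.items():
            assert cnt == merged.loc[v, "n_mated"]
        assert (assay.vials["n_mated"] <= assay.vials["n_females"]).all()
        assert not assay.matings["male_id"].duplicated().any()
        assert (assay.matings["latency_min"] <= 60).all()

    def test_mean_proportion_matches_markov_oracle(self, pop):
        h, window = 0.01, 30
        model = _constant_hazard_model(h)
        props = []
        for s in range(60):
            assay = sd.simulate_mating_assay(pop, model, window=window, seed=100 + s)
            props.append(assay.vials["n_mated"].to_numpy() / 5.0)
        props = np.concatenate(props)
        expected = _markov_expected_proportion(h, window)
        se = props.std(ddof=1) / np.sqrt(len(props))
        assert abs(props.mean() - expected) < 3 * se

    def test_window_must_be_positive(self, pop):
        with pytest.raises(ValueError):
            sd.simulate_mating_assay(pop, _constant_hazard_model(0.1), window=0)


class TestTruncationSelect:
    def test_first_k_latency_dominates_unselected(self, assay):
        k = 40
        ids = sd.truncation_select(assay, "first-k", k, seed=1)
        assert len(ids) == k == len(set(ids))
        lat = assay.matings.set_index("male_id")["latency_min"]
        unselected = lat.drop(index=ids)
        if len(unselected):
            assert lat.loc[ids].max() <= unselected.min()

    def test_k_fastest_are_smallest_latencies(self, assay):
        ids = sd.truncation_select(assay, "k-fastest", 30, seed=1)
        lat = assay.matings.sort_values(["latency_min", "tiebreak"])["latency_min"]
        np.testing.assert_array_equal(
            np.sort(assay.matings.set_index("male_id").loc[ids, "latency_min"]),
            np.sort(lat.iloc[:30].to_numpy()),
        )

    def test_k_random_reproducible(self, assay):
        a = sd.truncation_select(assay, "k-random", 50, seed=42)
        b = sd.truncation_select(assay, "k-random", 50, seed=42)
        np.testing.assert_array_equal(a, b)
        assert len(set(a)) == 50

    def test_shortfall_error_names_counts(self, assay):
        n_maters = len(assay.matings)
        with pytest.raises(ValueError, match=str(n_maters)):
            sd.truncation_select(assay, "first-k", n_maters + 5, seed=1)


class TestPoolSeq:
    def _fixed_freq_population(self, freq, n_flies=5, n_sites=100):
        """Population whose pool alt frequency is exactly `freq` at all sites."""
        n_founders = 10
        n_alt = int(round(freq * 2 * n_flies))
        dosage = np.zeros((n_founders, n_sites))
        dosage[:n_alt, :] = 2.0
        variants = pd.DataFrame(
            {"chrom": "2L", "pos": np.arange(1, n_sites + 1) * 10, "ref": "A", "alt": "T",
             "af": freq}
        )
        from matescan.datatypes import FounderPanel, GenotypeMatrix

        panel = FounderPanel(
            genotypes=GenotypeMatrix(
                [f"L{i}" for i in range(n_founders)], variants, dosage
            ),
            karyotypes=pd.DataFrame(index=[f"L{i}" for i in range(n_founders)]),
            wolbachia=pd.Series(False, index=[f"L{i}" for i in range(n_founders)]),
        )
        origin = np.arange(2 * n_flies, dtype=np.int16).reshape(n_flies, 2)
        origin = np.repeat(origin[:, :, None], n_sites, axis=2)
        return Population(panel=panel, founder_origin=origin,
                          is_male=np.ones(n_flies, bool), generation=0)

    def test_fixed_ref_gives_zero_alt_reads(self):
        pop = self._fixed_freq_population(0.0)
        pc = sd.simulate_pool_seq(pop, coverage_law=50, seed=1)
        assert (pc.alt_count == 0).all()
        assert (pc.coverage == 50).all()

    def test_fixed_alt_gives_all_alt_reads(self):
        pop = self._fixed_freq_population(1.0)
        pc = sd.simulate_pool_seq(pop, coverage_law=50, seed=1)
        np.testing.assert_array_equal(pc.alt_count, pc.coverage)

    def test_binomial_mean_unbiased(self):
        pop = self._fixed_freq_population(0.3, n_flies=5, n_sites=10_000)
        pc = sd.simulate_pool_seq(pop, coverage_law=100, seed=2)
        est = pc.frequencies()
        se = np.sqrt(0.3 * 0.7 / 100 / 10_000)
        assert abs(est.mean() - 0.3) < 3 * se

    def test_empty_pool_errors(self, aip):
        with pytest.raises(ValueError):
            sd.simulate_pool_seq(aip, member_idx=np.array([], dtype=int))


class TestLinePhenotypes:
    def test_zero_h2_gives_zero_genetic_variance(self):
        ph = sd.simulate_line_phenotypes(100, 10, h2_target=0.0, seed=5)
        vc = quantgen.estimate_h2(ph)
        assert vc.h2 < 0.05

    def test_seeded_rerun_identical(self):
        a = sd.simulate_line_phenotypes(20, 5, seed=8)
        b = sd.simulate_line_phenotypes(20, 5, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_proportions_bounded(self):
        ph = sd.simulate_line_phenotypes(50, 8, grand_mean=0.05, total_sd=0.2, seed=9)
        prop = ph["n_mated"] / ph["n_females"]
        assert (prop >= 0).all() and (prop <= 1).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sd.simulate_line_phenotypes(10, 5, h2_target=1.5)
        with pytest.raises(ValueError):
            sd.simulate_line_phenotypes(10, 5, grand_mean=0.0)


class TestTraitModel:
    def test_realized_h2_matches_target(self, aip):
        rng = np.random.default_rng(31)
        model = TraitModel.from_h2(aip, n_causal=10, h2=0.4, rng=rng)
        g = model.genetic_values(aip)
        realized = g.var() / (g.var() + model.env_sd**2)
        assert abs(realized - 0.4) < 0.02

    def test_equal_effect_magnitudes(self, aip):
        rng = np.random.default_rng(32)
        model = TraitModel.from_h2(
            aip, n_causal=5, h2=0.5, rng=rng, effect_dist="equal",
            causal_freq_range=(0.2, 0.8),
        )
        assert len(set(np.round(np.abs(model.effects), 12))) == 1
        freq = aip.alt_frequencies()[model.causal_idx]
        assert ((freq >= 0.2) & (freq <= 0.8)).all()


class TestSelectionExperiment:
    def test_two_controls_after_split_generation(self, forty_line_panel, aip):
        model = TraitModel.from_h2(aip, 10, 0.3, np.random.default_rng(41))
        traj, lines = sd.simulate_selection_experiment(
            forty_line_panel, model, aip, generations=4, second_control_generation=2,
            assay_males=100, control_assay_males=100, k=20, offspring_per_line=240,
            seed=42,
        )
        n_controls = traj.groupby("generation")["role"].apply(lambda r: (r == "control").sum())
        assert n_controls.loc[1] == 1
        assert n_controls.loc[3] == 2
        assert set(traj["role"]) == {"selected", "control"}
        assert (traj["proportion"] >= 0).all() and (traj["proportion"] <= 1).all()
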