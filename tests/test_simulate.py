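"""Synthetic-data generators: phenotype construction, Poisson plaques,
receptor-genotype cross matrices, reproducibility."""
import math

import numpy as np
import pytest

import phagemix as pm
from phagemix.simulate import (
    DEFAULT_SPOT_LADDER,
    paper_shape_genotypes,
    paper_shape_panel,
    substream,
)


class TestGrowthCurves:
    def test_noiseless_full_inhibition_calls_strong(self, config):
        cfg = pm.SimulationConfig(seed=config.seed, noise_sd_od=0.0)
        control, treated = pm.simulate_growth_curve("full_inhibition", cfg)
        call = pm.classify_inhibition(control, treated)
        assert control.endpoint - treated.endpoint > 0.1
        assert call.label is pm.InhibitionLabel.STRONG

    def test_noiseless_no_effect_calls_none(self, config):
        cfg = pm.SimulationConfig(seed=config.seed, noise_sd_od=0.0)
        control, treated = pm.simulate_growth_curve("no_effect", cfg)
        assert np.array_equal(control.od, treated.od)
        call = pm.classify_inhibition(control, treated)
        assert call.endpoint_diff == 0.0
        assert call.label is pm.InhibitionLabel.NONE

    def test_partial_plateau_between_baseline_and_control(self, config):
        cfg = pm.SimulationConfig(seed=config.seed, noise_sd_od=0.0)
        control, treated = pm.simulate_growth_curve("partial_inhibition", cfg)
        assert 0.1 < treated.endpoint < control.endpoint

    def test_transient_rejoins_control_by_endpoint(self, config):
        cfg = pm.SimulationConfig(seed=config.seed, noise_sd_od=0.0)
        control, treated = pm.simulate_growth_curve("transient_inhibition", cfg)
        mid = control.timepoints.size // 2
        assert treated.od[mid] < control.od[mid] - 0.1  # lags early
        assert abs(control.endpoint - treated.endpoint) < 0.05  # rejoined

    def test_default_grid_is_280min_20min_steps(self, config):
        control, _ = pm.simulate_growth_curve("no_effect", config)
        assert control.timepoints[0] == 0.0
        assert control.timepoints[-1] == 280.0
        assert np.all(np.diff(control.timepoints) == 20.0)

    def test_unknown_phenotype_rejected(self, config):
        with pytest.raises(ValueError):
            pm.simulate_growth_curve("lysogenic", config)


class TestPlaqueCounts:
    def test_poisson_mean_identity(self):
        # mean count = titer * volume * dilution = 1e9 * 0.1 * 1e-6 = 100
        counts = []
        rng = substream(3, "plaque")
        for _ in range(400):
            s = pm.simulate_plaque_counts(1e9, [1e-6], rng=rng)
            counts.append(s.records[0][1][0])
        assert np.mean(counts) == pytest.approx(100.0, rel=0.05)

    def test_zero_count_probability_closed_form(self):
        # mean 1e3 * 0.1 * 1e-6 = 1e-4; P(0) = exp(-1e-4) ~ 1
        rng = substream(4, "plaque")
        zeros = sum(
            pm.simulate_plaque_counts(1e3, [1e-6], rng=rng).records[0][1][0] == 0
            for _ in range(200)
        )
        assert zeros / 200 == pytest.approx(math.exp(-1e-4), abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pm.simulate_plaque_counts(0.0, [1e-6])
        with pytest.raises(ValueError):
            pm.simulate_plaque_counts(1e9, [1e-6], volume_ml=0.0)
        with pytest.raises(ValueError):
            pm.simulate_plaque_counts(1e9, [2.0])

    def test_estimator_recovers_titer(self):
        """Parameter recovery: relative bias < 5% over replicates with counts
        in the 30-300 window."""
        rng = substream(11, "plaque")
        estimates = []
        for _ in range(300):
            s = pm.simulate_plaque_counts(2e8, [1e-5], plates_per_dilution=3, rng=rng)
            estimates.append(pm.estimate_titer(s).mf)
        bias = (np.mean(estimates) - 2e8) / 2e8
        assert abs(bias) < 0.05


class TestCrossMatrix:
    def _toy(self):
        genotypes = [
            pm.ReceptorGenotype("g1", {"OmpC", "OmpA"}),
            pm.ReceptorGenotype("g2", {"OmpC", "LPS-core-A"}),
        ]
        phages = [
            pm.PhageRecord("pC", "E. coli", main_receptors={"OmpC"}),
            pm.PhageRecord("pA", "E. coli", main_receptors={"OmpA"}),
            pm.PhageRecord("pL", "E. coli", main_receptors={"LPS-core-A"}),
        ]
        return genotypes, phages

    def test_knockout_rule(self):
        genotypes, phages = self._toy()
        m = pm.simulate_cross_matrix(genotypes, phages, seed=7)
        # g1's OmpC-knockout variant: insensitive to pC, still sensitive to pA
        v = next(v for v in m.variants if v.inducing_phage_id == "pC"
                 and v.parent_strain_id == "g1")
        assert m.cell(v.variant_id, "pC") is pm.CellState.INSENSITIVE
        assert m.cell(v.variant_id, "pA") is pm.CellState.SENSITIVE

    def test_variant_only_arises_when_phage_can_infect(self):
        genotypes, phages = self._toy()
        m = pm.simulate_cross_matrix(genotypes, phages, seed=7)
        # g1 lacks LPS-core-A, so pL raises no variant from it
        assert not any(
            v.parent_strain_id == "g1" and v.inducing_phage_id == "pL"
            for v in m.variants
        )

    def test_deterministic_given_seed(self):
        genotypes, phages = self._toy()
        a = pm.simulate_cross_matrix(genotypes, phages, seed=9)
        b = pm.simulate_cross_matrix(genotypes, phages, seed=9)
        assert [v.variant_id for v in a.variants] == [v.variant_id for v in b.variants]
        assert all(
            a.cell(v.variant_id, p) == b.cell(v.variant_id, p)
            for v in a.variants for p in a.phages
        )

    def test_planted_core_phage_recovered(self):
        """A phage binding a receptor class never knocked out stays core."""
        genotypes = [
            pm.ReceptorGenotype(f"g{i}", {"OmpC", "OmpA", "LPS-core-A"})
            for i in range(6)
        ]
        phages = [
            pm.PhageRecord("p1", "E. coli", main_receptors={"OmpC"}),
            pm.PhageRecord("p2", "E. coli", main_receptors={"OmpA"}),
            pm.PhageRecord("p3", "E. coli", main_receptors={"OmpC"}),
            # the planted universally-binding phage: its receptor survives
            # every knockout because no other phage targets it
        ]
        core_phage = pm.PhageRecord("pcore", "E. coli",
                                    main_receptors={"LPS-core-A"})
        m = pm.simulate_cross_matrix(genotypes, phages + [core_phage], seed=7)
        # LPS-core-A is knocked out only in pcore-induced variants; exclude them
        others = [v.variant_id for v in m.variants
                  if v.inducing_phage_id != "pcore"]
        summary = pm.analyze_cross_sensitivity(m.subset(others))
        assert "pcore" in summary.core_phages

    def test_empty_phage_list_rejected(self):
        with pytest.raises(ValueError):
            pm.simulate_cross_matrix([pm.ReceptorGenotype("g", {"OmpC"})], [], 0)


class TestOtherGenerators:
    def test_spot_grid_threshold_semantics(self):
        grids = pm.simulate_spot_grid({"s1": 2e5, "s2": float("inf")}, seed=5)
        call1 = pm.call_sensitivity(grids["s1"])
        call2 = pm.call_sensitivity(grids["s2"])
        assert call1.label is pm.SensitivityLabel.SENSITIVE
        assert call1.lowest_positive_titer == 2e5
        assert call2.label is pm.SensitivityLabel.INSENSITIVE

    def test_biofilm_plate_suppression(self):
        m = pm.simulate_biofilm_plate(
            {"s1": 1.0}, {"s1": 0.2}, noise_sd=0.0, seed=1
        )[0]
        assert pm.ebc(m) == pytest.approx(80.0)

    def test_milk_counts_within_control_range(self, config):
        phage, control = pm.simulate_milk_counts(
            "s1", "E. coli", config, rng=substream(2, "milk")
        )
        mu = np.mean(np.log10(control.endpoint_counts))
        lo, hi = config.control_endpoint_ranges["E. coli"]
        assert np.log10(lo) - 0.5 < mu < np.log10(hi) + 0.5
        assert np.mean(np.log10(phage.endpoint_counts)) < mu

    def test_stability_series_decays(self):
        s = pm.simulate_stability_series(
            {"E. coli": 2.16e8, "S. aureus": 1.28e8}, noise_sd_log10=0.0, seed=0
        )
        table = pm.stability_percent(s)
        assert table.loc[0, "stability"] == 100
        assert (table["stability"].iloc[1:] < 100).all()
        assert table["stability"].iloc[-1] >= 90  # gentle storage decay

    def test_bit_reproducibility_across_generators(self, config):
        a1 = pm.simulate_growth_curve("partial_inhibition", config)
        a2 = pm.simulate_growth_curve("partial_inhibition", config)
        assert np.array_equal(a1[1].od, a2[1].od)
        b1 = pm.simulate_plaque_counts(1e9, [1e-6, 1e-7], 3, seed=config.seed)
        b2 = pm.simulate_plaque_counts(1e9, [1e-6, 1e-7], 3, seed=config.seed)
        assert b1.records == b2.records
        c1 = pm.simulate_stability_series({"x": 1e8}, seed=config.seed)
        c2 = pm.simulate_stability_series({"x": 1e8}, seed=config.seed)
        assert c1.component_titers == c2.component_titers

    def test_substreams_are_independent(self):
        # different assays draw from different streams of the same seed
        a = substream(0, "growth").random(4)
        b = substream(0, "plaque").random(4)
        assert not np.allclose(a, b)


class TestConfig:
    def test_phenotype_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pm.SimulationConfig(phenotype_mix={pm.Phenotype.NO_EFFECT: 0.5})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            pm.SimulationConfig(noise_sd_od=-0.1)

    def test_paper_shape_panel_counts(self, config):
        panel = paper_shape_panel(config)
        assert sum(p.host_species == "E. coli" for p in panel) == 5
        assert sum(p.host_species == "S. aureus" for p in panel) == 3
        genos = paper_shape_genotypes(config)
        assert sum(g.species == "E. coli" for g in genos) == 18
        assert sum(g.species == "S. aureus" for g in genos) == 15

    def test_default_ladder_matches_assay(self):
        assert DEFAULT_SPOT_LADDER == (2e8, 2e7, 2e6, 2e5, 2e4, 2e3)
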