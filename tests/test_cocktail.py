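"""Cocktail design, formulation and storage stability."""
import itertools

import numpy as np
import pytest

import phagemix as pm
from phagemix.cocktail import brute_force_coverage, round_1sig


def phage(pid, mains, species="E. coli", supports=()):
    return pm.PhageRecord(
        phage_id=pid, host_species=species,
        main_receptors=frozenset(mains), support_receptors=frozenset(supports),
    )


def random_lytic(rng, n_phages, n_strains, p_cover=0.45):
    strains = [f"s{i}" for i in range(n_strains)]
    return {
        f"p{j}": {
            s: ("strong" if rng.random() < p_cover else "none") for s in strains
        }
        for j in range(n_phages)
    }


class TestDesignCocktail:
    def test_singleton_optimum(self):
        lytic = {"p0": {"s1": "strong", "s2": "weak"}}
        design = pm.design_cocktail(lytic, [phage("p0", {"OmpC"})])
        assert design.selected == ("p0",)
        assert design.coverage == 1.0
        assert all(d == 1 for d in design.redundancy_depth.values())
        assert not any(design.resilience.values())  # single phage: no backup

    def test_planted_receptor_distinct_pair(self):
        # 4 phages x 6 strains; p0+p1 is the only 2-subset with full coverage
        strains = [f"s{i}" for i in range(6)]
        cover = {
            "p0": strains[:3],
            "p1": strains[3:],
            "p2": strains[1:4],
            "p3": strains[2:5],
        }
        lytic = {
            p: {s: ("strong" if s in c else "none") for s in strains}
            for p, c in cover.items()
        }
        panel = [
            phage("p0", {"OmpC"}),
            phage("p1", {"OmpA"}),
            phage("p2", {"OmpC"}),
            phage("p3", {"OmpA"}),
        ]
        design = pm.design_cocktail(lytic, panel, max_size=2)
        assert set(design.selected) == {"p0", "p1"}
        assert design.coverage == 1.0
        # brute force over all 15 non-empty subsets confirms the pair is optimal
        best_cov, best = brute_force_coverage(lytic, max_size=2)
        assert best_cov == 1.0 and set(best) == {"p0", "p1"}
        # receptor-distinct pair: every strain resilient iff covered twice
        for s, depth in design.redundancy_depth.items():
            assert design.resilience[s] == (depth >= 2)

    def test_receptor_diversity_breaks_coverage_ties(self):
        strains = ["s1", "s2", "s3", "s4"]
        lytic = {
            "pA": {"s1": "strong", "s2": "strong", "s3": "none", "s4": "none"},
            "pB": {"s1": "none", "s2": "none", "s3": "strong", "s4": "strong"},
            "pC": {"s3": "strong", "s4": "strong", "s1": "none", "s2": "none"},
        }
        panel = [
            phage("pA", {"OmpC"}),
            phage("pB", {"OmpA"}),  # distinct from pA
            phage("pC", {"OmpC"}),  # same class as pA
        ]
        design = pm.design_cocktail(lytic, panel, max_size=2)
        assert set(design.selected) == {"pA", "pB"}

    def test_mixed_species_panel_rejected(self):
        lytic = {"p0": {"s": "strong"}, "q0": {"s": "strong"}}
        panel = [phage("p0", {"OmpC"}), phage("q0", {"WTA"}, species="S. aureus")]
        with pytest.raises(ValueError, match="species"):
            pm.design_cocktail(lytic, panel)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            pm.design_cocktail({}, [])

    def test_coverage_monotone_in_panel_size(self, rng):
        lytic = random_lytic(rng, 6, 10)
        panel = [phage(p, {f"R{i}"}) for i, p in enumerate(sorted(lytic))]
        coverages = []
        for k in range(1, 7):
            sub = {p: lytic[p] for p in sorted(lytic)[:k]}
            design = pm.design_cocktail(sub, panel)
            coverages.append(design.coverage)
        assert coverages == sorted(coverages)

    def test_core_phage_from_cross_matrix(self, cross_matrix, phage_panel):
        """On the transcribed resistance data the alpha-GlcNAc binder is the
        core of the anti-S. aureus component."""
        strains = ["a", "b", "c", "d"]
        cover = {
            "351Saur083PP": {"a", "b"},
            "355Saur083PP": {"b", "c"},
            "357Saur119PP": {"d"},
        }
        lytic = {
            p: {s: ("strong" if s in c else "none") for s in strains}
            for p, c in cover.items()
        }
        panel = [p for p in phage_panel if p.host_species == "S. aureus"]
        design = pm.design_cocktail(
            lytic, panel, cross=cross_matrix.by_species("S. aureus")
        )
        assert "357Saur119PP" in design.core_phages

    def test_greedy_matches_union_coverage(self, rng):
        lytic = random_lytic(rng, 5, 9)
        panel = [phage(p, {f"R{i}"}) for i, p in enumerate(sorted(lytic))]
        design = pm.design_cocktail(lytic, panel)
        best_cov, _ = brute_force_coverage(lytic)
        assert design.coverage == pytest.approx(best_cov)


class TestFormulate:
    @pytest.mark.parametrize(
        "n,component,expected",
        [
            (5, 1e8, 2e7),  # five-phage component
            (3, 1e8, 3e7),  # three-phage component, rounded from 3.33e7
            (1, 2.5e8, 2.5e8),  # identity keeps the exact value
        ],
    )
    def test_equal_split(self, n, component, expected):
        f = pm.formulate(n, component)
        if n == 1:
            assert f.per_phage_titer == component
        else:
            assert f.per_phage_titer_reported == pytest.approx(expected)

    def test_reported_is_one_significant_digit(self):
        f = pm.formulate(3, 1e8)
        assert f.per_phage_titer == pytest.approx(1e8 / 3)
        assert f.per_phage_titer_reported == 3e7

    def test_accepts_phage_id_list(self):
        f = pm.formulate(["a", "b", "c", "d", "e"], 1e8)
        assert f.per_phage_titer_reported == 2e7

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            pm.formulate(0, 1e8)

    @pytest.mark.parametrize(
        "x,expected", [(3.33e7, 3e7), (2e7, 2e7), (9.6e8, 1e9), (0.0451, 0.05)]
    )
    def test_round_1sig(self, x, expected):
        assert round_1sig(x) == pytest.approx(expected)


class TestStabilityPercent:
    def test_reference_point_is_100(self):
        series = pm.StabilitySeries(
            months=(0, 3), component_titers={"c": (1e8, 1e8)}
        )
        table = pm.stability_percent(series)
        assert table.loc[0, "stability"] == 100
        assert table.loc[1, "stability"] == 100  # identical titer

    def test_printed_storage_table_reproduced(self, stability_series):
        table = pm.stability_percent(stability_series)
        assert list(table["stability"]) == [100, 97, 97, 98, 95, 94, 96, 95, 95]
        assert table.loc[0, "final_titer"] == pytest.approx(3.44e8)
        assert table.loc[1, "final_titer"] == pytest.approx(1.90e8, rel=5e-3)

    def test_scale_invariance_under_common_units(self, stability_series):
        table = pm.stability_percent(stability_series)
        # converting PFU/mL -> PFU/L multiplies every titer by 1000; %Log is
        # not invariant in general, but the ratio form keeps month 0 at 100
        scaled = pm.StabilitySeries(
            months=stability_series.months,
            component_titers={
                k: tuple(x * 1e3 for x in v)
                for k, v in stability_series.component_titers.items()
            },
        )
        t2 = pm.stability_percent(scaled)
        assert t2.loc[0, "stability"] == table.loc[0, "stability"] == 100

    def test_titer_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            pm.stability_percent(
                pm.StabilitySeries(months=(0,), component_titers={"c": (0.5,)})
            )


def test_greedy_bound_on_random_instances(rng):
    """Greedy coverage at any size cap k is >= (1 - 1/e) x brute-force optimum."""
    bound = 1 - 1 / np.e
    for _ in range(30):
        n_phages = int(rng.integers(2, 13))
        lytic = random_lytic(rng, n_phages, int(rng.integers(4, 10)))
        panel = [phage(p, {f"R{i}"}) for i, p in enumerate(sorted(lytic))]
        for k in (1, 2, 3):
            if k > n_phages:
                continue
            design = pm.design_cocktail(lytic, panel, max_size=k)
            best_cov, _ = brute_force_coverage(lytic, max_size=k)
            assert design.coverage >= bound * best_cov - 1e-12
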