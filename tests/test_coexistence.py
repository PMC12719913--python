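"""ZNGIs, invasion analysis, supply-plane maps, and diamond thresholds."""

import numpy as np
import pytest

from ddcoex import (
    ConfigError,
    FoodWebConfig,
    PredatorTraits,
    ResourceEnvironment,
    SpeciesTraits,
    classify_supply_point,
    coexistence_map,
    diamond_thresholds,
    invasion_boundary,
    invasion_growth_rate,
    r_star,
    single_resident_equilibrium,
    zngi,
)
from conftest import random_diamond_web


class TestRStar:
    def test_direct_formula(self):
        sp = SpeciesTraits(mu=[1.0], V=[1.0], m=0.1)
        assert r_star(sp) == pytest.approx(0.1)

    def test_diamond_fast_grower(self, diamond_web):
        sp = diamond_web(mq=0.0).species[0]
        assert r_star(sp) == pytest.approx(0.0357142857, rel=1e-8)

    def test_linear_in_mortality(self):
        lo = SpeciesTraits(mu=[2.0], V=[1.0], m=0.1)
        hi = SpeciesTraits(mu=[2.0], V=[1.0], m=0.2)
        assert r_star(hi) == pytest.approx(2 * r_star(lo))

    def test_zero_growth_coefficient_rejected(self):
        sp = SpeciesTraits(mu=[0.0, 1.0], V=[1.0, 1.0], m=0.1)
        with pytest.raises(ValueError):
            r_star(sp, resource=0)


class TestZNGI:
    def test_invasion_line_and_intercepts(self, coexisting_pair):
        sp1 = coexisting_pair(mq=0.01).species[0]
        line = zngi(sp1, density=0.0)
        assert line.level == pytest.approx(0.1)
        r1, r2 = line.intercepts()
        assert r1 == pytest.approx(0.1) and r2 == pytest.approx(0.5)

    def test_invasion_zngi_independent_of_mq(self, coexisting_pair):
        lines = [zngi(coexisting_pair(mq=mq).species[0], 0.0) for mq in (0, 0.01, 0.1)]
        assert len({(l.coefficients, l.level) for l in lines}) == 1

    def test_mq_zero_collapses_all_equilibrium_lines(self):
        sp = SpeciesTraits(mu=[1.0, 0.5], V=[1, 1], m=0.1, mq=0.0)
        assert zngi(sp, 0.0).level == zngi(sp, 5.0).level

    def test_positive_density_shifts_line_outward(self):
        sp = SpeciesTraits(mu=[1.0, 0.5], V=[1, 1], m=0.1, mq=0.02)
        assert zngi(sp, 3.0).level == pytest.approx(0.1 + 0.02 * 3.0)
        assert zngi(sp, 3.0).level > sp.m

    def test_requires_two_resources(self):
        sp = SpeciesTraits(mu=[1.0], V=[1.0], m=0.1)
        with pytest.raises(ValueError):
            zngi(sp)


class TestInvasionGrowth:
    def test_empty_environment_zero_at_rstar(self):
        sp = SpeciesTraits(mu=[2.0], V=[1.0], m=0.1)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[0.05], a=1.0))
        # below R* = 0.05: no resident equilibrium at all
        assert single_resident_equilibrium(cfg, 0) is None
        cfg2 = cfg.with_supply([0.2])
        eq = single_resident_equilibrium(cfg2, 0)
        assert eq is not None

    def test_identical_invader_sees_self_limitation_headroom(self):
        """An invader with the resident's own traits has G = mq * N_hat: the
        resident's density-dependent loss is headroom for a rare clone."""
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.05)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[2.0], a=1.0))
        eq = single_resident_equilibrium(cfg, 0)
        G = invasion_growth_rate(sp, eq)
        assert G == pytest.approx(sp.mq * eq.state.N[0], rel=1e-10)
        assert G > 0

    def test_invader_present_in_resident_set_rejected(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.05)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[2.0], a=1.0))
        eq = single_resident_equilibrium(cfg, 0)
        with pytest.raises(ValueError):
            invasion_growth_rate(sp, eq, index=0)


class TestDiamondThresholds:
    def test_printed_parameters_reproduce_derived_values(self, diamond_web):
        s21, s12 = diamond_thresholds(diamond_web(mq=0.0))
        assert s21 == pytest.approx(0.133335, rel=1e-4)
        assert s12 == pytest.approx(0.143792, rel=1e-4)
        w21, w12 = diamond_thresholds(diamond_web(mq=0.01))
        assert w21 == pytest.approx(0.133278, rel=1e-4)
        assert w12 == pytest.approx(0.145352, rel=1e-4)
        assert w21 < s21 and w12 > s12  # interval strictly widens

    def test_thresholds_monotone_in_mq(self, diamond_web):
        out = [diamond_thresholds(diamond_web(mq=mq)) for mq in (0, 0.005, 0.01, 0.02)]
        s21s, s12s = zip(*out)
        assert np.all(np.diff(s21s) < 0) and np.all(np.diff(s12s) > 0)

    def test_matches_numeric_invasion_bisection(self, diamond_web):
        rng = np.random.default_rng(21)
        webs = [diamond_web(mq=0.0), diamond_web(mq=0.01)]
        webs += [random_diamond_web(rng) for _ in range(5)]
        for cfg in webs:
            s21, s12 = diamond_thresholds(cfg)
            b21 = invasion_boundary(cfg, invader=1, resident=0, axis=0,
                                    bracket=(0.3 * s21, 0.5 * (s21 + s12)))
            b12 = invasion_boundary(cfg, invader=0, resident=1, axis=0,
                                    bracket=(0.5 * (s21 + s12), 3 * s12))
            assert b21 == pytest.approx(s21, rel=1e-6)
            assert b12 == pytest.approx(s12, rel=1e-6)

    def test_ordering_preconditions_named(self, diamond_web):
        cfg = diamond_web(mq=0.0)
        cfg.species[0].mu = np.array([1.0])  # now mu1 < mu2
        with pytest.raises(ConfigError, match="mu1 > mu2"):
            diamond_thresholds(cfg)

    def test_no_trade_off_degenerates_to_zero(self):
        sp1 = SpeciesTraits(mu=[2.0], V=[1.0], g=[3.0], m=0.1, mq=0.0)
        sp2 = SpeciesTraits(mu=[1.0], V=[1.0], g=[3.0], m=0.1, mq=0.0)
        cfg = FoodWebConfig(
            [sp1, sp2], [PredatorTraits(f=[1.0, 1.0], mp=0.1)],
            ResourceEnvironment(s=[1.0], a=1.0),
        )
        assert diamond_thresholds(cfg) == (0.0, 0.0)


class TestClassification:
    def test_region_of_no_species(self, coexisting_pair):
        out = classify_supply_point(coexisting_pair(mq=0.01, s=(0.05, 0.05)))
        assert out.label == "none" and out.detail == ()

    def test_coexistence_wedge_and_exclusion_flanks(self, coexisting_pair):
        assert classify_supply_point(coexisting_pair(mq=0.0, s=(0.3, 0.3))).label == "coexistence"
        assert classify_supply_point(coexisting_pair(mq=0.0, s=(1.4, 0.05))).label == "species_1_wins"
        assert classify_supply_point(coexisting_pair(mq=0.0, s=(0.05, 1.4))).label == "species_2_wins"

    def test_priority_effect_low_supply_coexistence_high_supply(self, priority_pair):
        assert classify_supply_point(priority_pair(mq=0.0, s=(0.5, 0.5))).label == "priority_effect"
        low = classify_supply_point(priority_pair(mq=0.01, s=(0.1, 0.175)))
        assert low.label == "priority_effect"
        high = classify_supply_point(priority_pair(mq=0.01, s=(3.0, 3.0)))
        assert high.label == "coexistence"

    def test_priority_region_unbounded_only_without_density_dependence(self, priority_pair):
        for scale in (1.0, 10.0, 100.0):
            out = classify_supply_point(priority_pair(mq=0.0, s=(0.5 * scale, 0.5 * scale)))
            assert out.label == "priority_effect"
            out = classify_supply_point(priority_pair(mq=0.01, s=(0.5 * scale, 0.5 * scale)))
            assert out.label != "priority_effect"

    def test_three_species_overlap_only_with_density_dependence(self, three_species_web):
        out = classify_supply_point(three_species_web(mq=0.01, s=(1.5, 1.5)))
        assert out.label == "coexistence" and set(out.detail) == {0, 1, 2}
        out0 = classify_supply_point(three_species_web(mq=0.0, s=(1.5, 1.5)))
        assert len(out0.detail) < 3


class TestInvasionBoundary:
    def test_bracket_without_sign_change_rejected(self, diamond_web):
        cfg = diamond_web(mq=0.0)
        s21, s12 = diamond_thresholds(cfg)
        with pytest.raises(ValueError, match="sign change"):
            invasion_boundary(cfg, invader=1, resident=0, axis=0,
                              bracket=(s21 * 1.01, s12 * 0.99))

    def test_mq_zero_boundary_expands_linearly_with_supply(self, coexisting_pair):
        """Without density dependence the invasion boundary approaches a ray
        from the origin: the boundary supply ratio s2*/s1 converges at three
        increasing magnifications."""
        cfg = coexisting_pair(mq=0.0)
        ratios = []
        for s1 in (3.0, 30.0, 300.0):
            b = invasion_boundary(cfg.with_supply([s1, 1.0]), invader=1, resident=0,
                                  axis=1, bracket=(1e-3 * s1, 10 * s1))
            ratios.append(b / s1)
        steps = np.abs(np.diff(ratios))
        assert steps[1] < steps[0]  # converging
        assert steps[1] / ratios[-1] < 0.05


class TestCoexistenceMap:
    def test_density_dependence_expands_coexistence_area(self, coexisting_pair):
        grid = np.linspace(0.01, 1.5, 40)
        n0 = coexistence_map(coexisting_pair(0.0), grid, grid).count("coexistence")
        n1 = coexistence_map(coexisting_pair(0.01), grid, grid).count("coexistence")
        assert n1 > n0

    def test_coexistence_area_monotone_on_mq_grid(self, coexisting_pair):
        grid = np.linspace(0.01, 1.5, 15)
        counts = [
            coexistence_map(coexisting_pair(mq), grid, grid).count("coexistence")
            for mq in (0.0, 0.005, 0.01, 0.02)
        ]
        assert np.all(np.diff(counts) >= 0)

    def test_one_species_map_boundary_at_invasion_zngi(self):
        sp = SpeciesTraits(mu=[1.0, 0.5], V=[1.0, 1.0], m=0.1, mq=0.01)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[1, 1], a=1.0))
        grid = np.linspace(0.01, 0.4, 25)
        cmap = coexistence_map(cfg, grid, grid)
        labels = cmap.labels()
        assert set(labels.ravel()) == {"none", "species_1_wins"}
        for i, s1 in enumerate(grid):
            for j, s2 in enumerate(grid):
                expected = "species_1_wins" if s1 + 0.5 * s2 > 0.1 else "none"
                assert labels[i, j] == expected

    def test_diamond_1d_map_interval_widens_with_mq(self, diamond_web):
        grid = np.linspace(0.1, 0.2, 101)
        c0 = coexistence_map(diamond_web(0.0), grid).count("coexistence")
        c1 = coexistence_map(diamond_web(0.01), grid).count("coexistence")
        assert c1 > c0

    def test_long_format_export(self, coexisting_pair):
        grid = np.linspace(0.1, 0.5, 5)
        df = coexistence_map(coexisting_pair(0.01), grid, grid).to_dataframe()
        assert list(df.columns) == ["s1", "s2", "label", "survivors"]
        assert len(df) == 25
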