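"""Analytical abundance predictions against simulated equilibria."""

import numpy as np
import pytest

from ddcoex import (
    FoodWebConfig,
    PredatorTraits,
    ResourceEnvironment,
    SpeciesTraits,
    bottom_up_control,
    bottom_up_equilibrium,
    direct_density,
    find_equilibrium,
    general_control,
    top_down_control,
    top_down_equilibrium,
)
from conftest import random_bottom_up_guild, random_top_down_guild


class TestGeneralControl:
    def test_single_species_equals_mean(self):
        N = general_control(2.0, np.array([0.3]), 0.3, mq=0.01)
        assert N[0] == pytest.approx(2.0)

    def test_symmetric_pair_splits_by_growth_advantage(self):
        G_bar, delta, mq = 0.2, 0.05, 0.01
        N = general_control(3.0, np.array([G_bar + delta, G_bar - delta]), G_bar, mq)
        np.testing.assert_allclose(N, [3.0 + delta / mq, 3.0 - delta / mq])

    def test_mq_zero_refused(self):
        with pytest.raises(ValueError, match="mq > 0"):
            general_control(1.0, np.array([0.1]), 0.1, mq=0.0)


class TestBottomUp:
    def test_single_species_both_expressions_agree_at_true_equilibrium(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.05)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[2.0], a=1.0))
        R_hat, pred = bottom_up_equilibrium(cfg)
        flux_form = 1.0 * (2.0 - R_hat) / (2.0 * R_hat)
        growth_form = (1.0 * R_hat - 0.1) / 0.05
        assert pred.N_hat[0] == pytest.approx(flux_form, rel=1e-10)
        assert pred.N_hat[0] == pytest.approx(growth_form, rel=1e-10)

    def test_identical_species_all_at_mean(self):
        sp = lambda: SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.02)
        cfg = FoodWebConfig([sp() for _ in range(4)], [], ResourceEnvironment(s=[3.0], a=1.0))
        _, pred = bottom_up_equilibrium(cfg)
        np.testing.assert_allclose(pred.N_hat, pred.N_bar, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_ode_equilibrium(self, seed):
        rng = np.random.default_rng(1000 + seed)
        cfg = random_bottom_up_guild(rng)
        eq = find_equilibrium(cfg)
        assert eq.converged
        pred = bottom_up_control(cfg, eq.state.R[0])
        mask = eq.state.N > 1e-6
        rel = np.abs(pred.N_hat[mask] - eq.state.N[mask]) / eq.state.N[mask]
        assert np.max(rel) < 1e-4
        assert set(pred.survivors) == set(eq.survivors)

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(77)
        cfg = random_bottom_up_guild(rng, n=6, mq=0.01)
        R_hat, pred = bottom_up_equilibrium(cfg)
        assert pred.weighted_mean_density() == pytest.approx(pred.N_bar, rel=1e-12)

    def test_dropped_species_reported_infeasible_not_clipped(self):
        # a species far below the others' R* cannot be in the coexisting set
        mus = [2.0, 1.8, 0.25]
        species = [SpeciesTraits(mu=[m_], V=[2 * m_], m=0.1, mq=0.01) for m_ in mus]
        cfg = FoodWebConfig(species, [], ResourceEnvironment(s=[1.0], a=1.0))
        _, pred = bottom_up_equilibrium(cfg)
        assert 2 not in pred.survivors
        assert pred.N_hat[2] == 0.0
        assert pred.N_hat[0] > 0 and pred.N_hat[1] > 0

    def test_invalid_resource_level_rejected(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.05)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[2.0], a=1.0))
        with pytest.raises(ValueError, match="R_hat"):
            bottom_up_control(cfg, R_hat=2.5)

    def test_mq_zero_directed_to_classic_limit(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.0)
        cfg = FoodWebConfig([sp], [], ResourceEnvironment(s=[2.0], a=1.0))
        with pytest.raises(ValueError, match="classic resource competition"):
            bottom_up_control(cfg, R_hat=0.5)


class TestTopDown:
    def test_equal_assimilation_subsistence_density(self):
        n, f = 4, 0.5
        species = [
            SpeciesTraits(mu=[1.0], V=[2.0], g=[1.0], m=0.1, mq=0.01)
            for _ in range(n)
        ]
        cfg = FoodWebConfig(
            species, [PredatorTraits(f=[f] * n, mp=0.1)],
            ResourceEnvironment(s=[1.0], a=1.0, fixed=True),
        )
        pred = top_down_control(cfg, R=[1.0], P_hat=0.5)
        assert pred.N_bar == pytest.approx(0.1 / (n * f))

    def test_single_prey_is_predator_subsistence(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], g=[1.0], m=0.1, mq=0.01)
        cfg = FoodWebConfig(
            [sp], [PredatorTraits(f=[0.8], mp=0.1)],
            ResourceEnvironment(s=[1.0], a=1.0, fixed=True),
        )
        P, pred = top_down_equilibrium(cfg)
        assert pred.N_hat[0] == pytest.approx(0.1 / 0.8, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 4, 6])
    def test_matches_ode_equilibrium(self, seed):
        rng = np.random.default_rng(100 + seed)
        cfg = random_top_down_guild(rng)
        eq = find_equilibrium(cfg)
        assert eq.converged
        mask = eq.state.N > 1e-6
        pred = top_down_control(cfg, eq.state.R, eq.state.P[0])
        rel = np.abs(pred.N_hat[mask] - eq.state.N[mask]) / eq.state.N[mask]
        assert np.max(rel) < 1e-4

    def test_zero_total_assimilation_rejected(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], g=[1.0], m=0.1, mq=0.01)
        cfg = FoodWebConfig(
            [sp], [PredatorTraits(f=[0.5], mp=0.1)],
            ResourceEnvironment(s=[1.0], a=1.0, fixed=True),
        )
        with pytest.raises(ValueError):
            top_down_control(cfg, R=[1.0], P_hat=0.1, candidates=np.array([], dtype=int))


class TestDirectDensity:
    def test_zero_growth_zero_density(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.01)
        assert direct_density(sp, R=[0.1]) == 0.0

    def test_doubling_mq_halves_density(self):
        lo = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.01)
        hi = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.02)
        assert direct_density(lo, R=[0.5]) == pytest.approx(2 * direct_density(hi, R=[0.5]))

    def test_equals_simulated_interior_equilibrium(self, diamond_web):
        cfg = diamond_web(mq=0.01, s=0.139)
        eq = find_equilibrium(cfg)
        assert eq.converged
        for i, sp in enumerate(cfg.species):
            assert direct_density(sp, eq.state.R, eq.state.P) == pytest.approx(
                eq.state.N[i], rel=1e-6
            )

    def test_mq_zero_refused(self):
        sp = SpeciesTraits(mu=[1.0], V=[2.0], m=0.1, mq=0.0)
        with pytest.raises(ValueError):
            direct_density(sp, R=[0.5])


class TestDecompositionEquivalence:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_guild_and_pointwise_forms_agree_at_equilibrium(self, seed):
        """The contrast-based guild decomposition and the pointwise G/mq
        evaluation give identical densities at a simulated equilibrium."""
        rng = np.random.default_rng(seed)
        cfg = random_bottom_up_guild(rng, n=int(rng.integers(2, 8)), mq=0.01)
        eq = find_equilibrium(cfg)
        assert eq.converged
        mask = eq.state.N > 1e-6
        guild = bottom_up_control(cfg, eq.state.R[0])
        for i in np.flatnonzero(mask):
            point = direct_density(cfg.species[i], eq.state.R)
            assert guild.N_hat[i] == pytest.approx(point, rel=1e-6)
            assert guild.N_hat[i] == pytest.approx(eq.state.N[i], rel=1e-4)


def test_richer_survivor_set_with_stronger_density_dependence():
    """In a fixed guild the number of feasible species never shrinks as mq
    grows: weaker competitors gain headroom."""
    rng = np.random.default_rng(5)
    mu = np.sort(rng.uniform(0.5, 2.0, 8))[::-1]
    counts = []
    for mq in (0.002, 0.01, 0.05, 0.2):
        species = [SpeciesTraits(mu=[m_], V=[m_ / 0.3], m=0.1, mq=mq) for m_ in mu]
        cfg = FoodWebConfig(species, [], ResourceEnvironment(s=[1.0], a=1.0))
        _, pred = bottom_up_equilibrium(cfg)
        counts.append(len(pred.survivors))
    assert np.all(np.diff(counts) >= 0)
    assert counts[-1] > counts[0]
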