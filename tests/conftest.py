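"""Shared fixtures: the printed figure parameter sets and fast solver options."""

import numpy as np
import pytest

from ddcoex import (
    FoodWebConfig,
    PredatorTraits,
    ResourceEnvironment,
    SolverOptions,
    SpeciesTraits,
)


def make_two_generalists(mq: float, V1, V2, s=(0.3, 0.3)) -> FoodWebConfig:
    """Two species on two substitutable resources (growth matrix of the
    coexisting-generalists illustration)."""
    sp1 = SpeciesTraits(mu=[1.0, 0.2], V=V1, m=0.1, mq=mq)
    sp2 = SpeciesTraits(mu=[0.5, 0.5], V=V2, m=0.1, mq=mq)
    return FoodWebConfig([sp1, sp2], [], ResourceEnvironment(s=list(s), a=1.0))


@pytest.fixture
def coexisting_pair():
    """Trade-off consumption pattern: each species eats more of its preferred
    resource; generalists coexist in a supply wedge."""

    def factory(mq: float, s=(0.3, 0.3)) -> FoodWebConfig:
        return make_two_generalists(mq, V1=[3.3, 0.67], V2=[1.67, 1.67], s=s)

    return factory


@pytest.fixture
def priority_pair():
    """Reversed consumption pattern (each species eats more of its less
    preferred resource): classic priority-effect configuration."""

    def factory(mq: float, s=(0.3, 0.3)) -> FoodWebConfig:
        return make_two_generalists(mq, V1=[1.1, 1.8], V2=[2.2, 0.6], s=s)

    return factory


@pytest.fixture
def three_species_web():
    """Two specialists plus one generalist on two resources."""

    def factory(mq: float, s=(1.0, 1.0)) -> FoodWebConfig:
        sp = [
            SpeciesTraits(mu=[0.165, 0.069], V=[0.55, 0.23], m=0.1, mq=mq),
            SpeciesTraits(mu=[0.072, 0.171], V=[0.24, 0.57], m=0.1, mq=mq),
            SpeciesTraits(mu=[0.15, 0.15], V=[0.5, 0.5], m=0.1, mq=mq),
        ]
        return FoodWebConfig(sp, [], ResourceEnvironment(s=list(s), a=1.0))

    return factory


@pytest.fixture
def diamond_web():
    """Diamond food web: two prey, one resource, one shared predator, with
    the gleaner-defender trade-off (species 1 grows faster, species 2 is
    better defended)."""

    def factory(mq: float, s: float = 0.14) -> FoodWebConfig:
        sp1 = SpeciesTraits(mu=[2.8], V=[4.2], g=[8.7], m=0.1, mq=mq)
        sp2 = SpeciesTraits(mu=[1.2], V=[1.8], g=[1.725], m=0.1, mq=mq)
        pred = PredatorTraits(f=[5.8, 1.15], mp=0.1)
        return FoodWebConfig([sp1, sp2], [pred], ResourceEnvironment(s=[s], a=1.0))

    return factory


@pytest.fixture
def fast_options() -> SolverOptions:
    return SolverOptions(t_max=5e3, rtol=1e-8, atol=1e-10)


def random_bottom_up_guild(rng: np.random.Generator, n=None, mq=None) -> FoodWebConfig:
    """Seeded random single-resource guild with a fixed yield."""
    n = int(rng.integers(2, 11)) if n is None else n
    mq = float(rng.choice([0.005, 0.01, 0.05])) if mq is None else mq
    mu = np.sort(rng.uniform(0.3, 2.0, n))[::-1]
    species = [
        SpeciesTraits(mu=[m_], V=[m_ / 0.3], m=0.1, mq=mq) for m_ in mu
    ]
    s = float(rng.uniform(0.5, 10.0))
    return FoodWebConfig(species, [], ResourceEnvironment(s=[s], a=1.0))


def random_top_down_guild(rng: np.random.Generator, n=None, mq=None) -> FoodWebConfig:
    """Seeded random guild constrained by one shared predator; resources fixed."""
    n = int(rng.integers(2, 11)) if n is None else n
    mq = float(rng.choice([0.005, 0.01, 0.05])) if mq is None else mq
    mu = rng.uniform(0.3, 1.5, n)
    g = rng.uniform(0.5, 3.0, n)
    f = rng.uniform(0.5, 2.0, n) * g
    species = [
        SpeciesTraits(mu=[m_], V=[m_ / 0.3], g=[g_], m=0.1, mq=mq)
        for m_, g_ in zip(mu, g)
    ]
    env = ResourceEnvironment(s=[float(rng.uniform(0.5, 2.0))], a=1.0, fixed=True)
    return FoodWebConfig(species, [PredatorTraits(f=f, mp=0.1)], env)


def random_diamond_web(rng: np.random.Generator) -> FoodWebConfig:
    """Random diamond web satisfying the gleaner-defender stability ordering
    with a nonempty coexistence interval."""
    from ddcoex import diamond_thresholds

    while True:
        mu1 = rng.uniform(1.5, 3.5)
        mu2 = rng.uniform(0.5, mu1 * 0.7)
        g1 = rng.uniform(4, 12)
        g2 = rng.uniform(0.5, g1 * 0.5)
        if g1 * mu2 - g2 * mu1 <= 0:
            continue
        f1, f2 = rng.uniform(2, 8), rng.uniform(0.5, 2)
        V1, V2 = rng.uniform(2, 6), rng.uniform(1, 3)
        mq = float(rng.choice([0.0, 0.005, 0.01]))
        sp1 = SpeciesTraits(mu=[mu1], V=[V1], g=[g1], m=0.1, mq=mq)
        sp2 = SpeciesTraits(mu=[mu2], V=[V2], g=[g2], m=0.1, mq=mq)
        cfg = FoodWebConfig(
            [sp1, sp2],
            [PredatorTraits(f=[f1, f2], mp=0.1)],
            ResourceEnvironment(s=[1.0], a=1.0),
        )
        s21, s12 = diamond_thresholds(cfg)
        if s21 > 0 and s12 > s21:
            return cfg
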