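"""Mutual-invasibility analysis: ZNGIs, invasion growth rates, supply-plane
coexistence maps, and the analytic diamond-web coexistence thresholds.

The classification of a supply point follows the graphical-analysis region
taxonomy: *none* (supply below every invasion ZNGI), *competitive exclusion*
(only one species can invade the other's resident equilibrium),
*coexistence* (mutual invasibility), and *priority effect* (each species
persists alone but neither can invade the other's resident state).
Density-dependent mortality leaves invasion ZNGIs untouched but lifts
equilibrium resource levels, bending invasion boundaries and widening the
coexistence region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import (
    CommunityState,
    EquilibriumResult,
    SolverOptions,
    default_initial_state,
    find_equilibrium,
)
from .foodweb import ConfigError, FoodWebConfig, SpeciesTraits

__all__ = [
    "ZNGILine",
    "SupplyPointOutcome",
    "CoexistenceMap",
    "r_star",
    "zngi",
    "single_resident_equilibrium",
    "invasion_growth_rate",
    "classify_supply_point",
    "invasion_boundary",
    "coexistence_map",
    "diamond_thresholds",
]


# --------------------------------------------------------------------------
# ZNGIs and R*


def r_star(species: SpeciesTraits, resource: int = 0) -> float:
    """Minimum single-resource requirement R* = m / mu_j.

    Independent of mq: density-dependent mortality vanishes at zero density,
    so the invasion requirement is unchanged.
    """
    mu = species.mu[resource]
    if mu <= 0:
        raise ValueError(
            f"R* undefined: species has zero growth coefficient on resource {resource}"
        )
    return species.m / mu


@dataclass(frozen=True)
class ZNGILine:
    """Zero net growth isocline mu_1 R_1 + mu_2 R_2 = level in the resource plane."""

    coefficients: tuple[float, float]
    level: float
    species: int = 0

    def intercepts(self) -> tuple[float, float]:
        """Axis intercepts (R1 at R2=0, R2 at R1=0); inf where mu_j = 0."""
        c1, c2 = self.coefficients
        return (
            self.level / c1 if c1 > 0 else np.inf,
            self.level / c2 if c2 > 0 else np.inf,
        )


def zngi(species: SpeciesTraits, density: float = 0.0, index: int = 0) -> ZNGILine:
    """ZNGI of a two-resource species at the given density.

    ``density=0`` gives the invasion ZNGI (level = m, independent of mq);
    positive density gives the outward-shifted equilibrium ZNGI with
    level = m + mq * N**(x-1).
    """
    if len(species.mu) != 2:
        raise ValueError("graphical ZNGI analysis requires exactly two resources")
    if density < 0:
        raise ValueError("density must be nonnegative")
    level = species.m + species.mq * density ** (species.x - 1.0)
    return ZNGILine(
        coefficients=(float(species.mu[0]), float(species.mu[1])),
        level=float(level),
        species=index,
    )


# --------------------------------------------------------------------------
# Resident equilibria (algebraic fast paths with ODE fallback)


def _sub_config(config: FoodWebConfig, keep: Sequence[int]) -> FoodWebConfig:
    """Config restricted to the given consumer species (predators retained)."""
    keep = list(keep)
    species = [config.species[i] for i in keep]
    predators = [
        replace(pr, f=pr.f[keep]) for pr in config.predators
    ]
    return FoodWebConfig(species, predators, config.environment)


def _embed(config: FoodWebConfig, keep: Sequence[int], sub: EquilibriumResult) -> EquilibriumResult:
    N = np.zeros(config.n_species)
    N[list(keep)] = sub.state.N
    state = CommunityState(N=N, P=sub.state.P, R=sub.state.R, t=sub.state.t)
    survivors = tuple(sorted(int(keep[i]) for i in sub.survivors))
    return replace(sub, state=state, survivors=survivors)


def _alone_density(config: FoodWebConfig, i: int) -> float | None:
    """Equilibrium density of species i alone (no predators); None if infeasible."""
    sp = config.species[i]
    env = config.environment
    s, a = env.s, env.a

    if env.fixed:
        G0 = float(sp.mu @ s - sp.m)
        if G0 <= 0:
            return None
        if sp.mq <= 0:
            raise ValueError(
                "species on fixed (non-depletable) resources has unbounded growth "
                "without density-dependent mortality"
            )
        return float((G0 / sp.mq) ** (1.0 / (sp.x - 1.0)))

    def growth(N: float) -> float:
        R = a * s / (a + sp.V * N)
        return float(sp.mu @ R - sp.m - sp.mq * N ** (sp.x - 1.0))

    if growth(0.0) <= 0:
        return None
    hi = 1.0
    while growth(hi) > 0:
        hi *= 4.0
        if hi > 1e12:
            raise RuntimeError("no single-species equilibrium below density 1e12")
    return float(brentq(growth, 0.0, hi, xtol=1e-14, rtol=1e-14))


def single_resident_equilibrium(
    config: FoodWebConfig, i: int, options: SolverOptions | None = None
) -> EquilibriumResult | None:
    """Equilibrium of species ``i`` as sole consumer (with any persisting predators).

    Solved algebraically for predator-free webs (scalar root in N) and for a
    single predator (predator subsistence N = mp/f, resource balance, prey
    zero-growth for P); other structures fall back to ODE equilibration of
    the restricted community.  Returns None when species i cannot persist at
    all (supply below its invasion ZNGI).
    """
    options = options or SolverOptions()
    sp = config.species[i]
    env = config.environment
    s, a = env.s, env.a
    n, l = config.n_species, config.n_predators

    N_alone = _alone_density(config, i)
    if N_alone is None:
        return None

    def result(Ni: float, P: np.ndarray, R: np.ndarray) -> EquilibriumResult:
        N = np.zeros(n)
        N[i] = Ni
        pred = tuple(int(h) for h in np.flatnonzero(P >= options.extinction_threshold))
        return EquilibriumResult(
            state=CommunityState(N=N, P=P, R=R, t=np.inf),
            survivors=(i,),
            predator_survivors=pred,
            converged=True,
            oscillatory=False,
            residual=0.0,
            t_end=np.inf,
            extinction_threshold=options.extinction_threshold,
        )

    def resources_at(Ni: float) -> np.ndarray:
        if env.fixed:
            return s.copy()
        return a * s / (a + sp.V * Ni)

    if l == 0:
        return result(N_alone, np.zeros(0), resources_at(N_alone))

    # which predators could invade the predator-free resident state?
    invaders = [
        h for h in range(l)
        if config.predators[h].f[i] * N_alone > config.predators[h].mp
    ]
    if not invaders:
        return result(N_alone, np.zeros(l), resources_at(N_alone))
    if len(invaders) == 1:
        h = invaders[0]
        pr = config.predators[h]
        g = sp.g[h]
        if g > 0:
            Ni = pr.mp / pr.f[i]
            R = resources_at(Ni)
            P_h = float(sp.mu @ R - sp.m - sp.mq * Ni ** (sp.x - 1.0)) / g
            if P_h > 0:
                P = np.zeros(l)
                P[h] = P_h
                return result(Ni, P, R)
        # predator invades but cannot regulate the prey (g = 0 or P <= 0)

    # general case: equilibrate the restricted community numerically
    sub = _sub_config(config, [i])
    eq = find_equilibrium(sub, options=options)
    if not (eq.converged or eq.oscillatory):
        raise RuntimeError(
            f"resident equilibrium for species {i} did not converge (t={eq.t_end:g})"
        )
    return _embed(config, [i], eq)


# --------------------------------------------------------------------------
# Invasion analysis


def invasion_growth_rate(
    invader: SpeciesTraits,
    resident_eq: EquilibriumResult,
    index: int | None = None,
) -> float:
    """Per-capita growth of a rare invader at the resident community's equilibrium.

    G = sum_j mu_j R_hat_j - m - sum_h g_h P_hat_h; the invader's own
    density-dependent loss is absent because it is rare.
    """
    if index is not None and index in resident_eq.survivors:
        raise ValueError(
            f"species {index} is part of the resident community; invasion growth "
            "is defined only for absent species"
        )
    R, P = resident_eq.state.R, resident_eq.state.P
    G = float(invader.mu @ R - invader.m)
    if len(invader.g) and len(P):
        G -= float(invader.g @ P)
    return G


@dataclass
class SupplyPointOutcome:
    """Classified outcome at one supply point."""

    label: str  # none | species_<i>_wins | coexistence | priority_effect
    detail: tuple[int, ...]  # winner / survivor indices (0-based)
    invasion_matrix: np.ndarray | None = None  # [i, j]: i invades resident j


def _pair_label(i: int, j: int, feas: np.ndarray, inv: np.ndarray) -> tuple[str, tuple[int, ...]]:
    if not feas[i] and not feas[j]:
        return "none", ()
    if feas[i] and not feas[j]:
        return f"species_{i + 1}_wins", (i,)
    if feas[j] and not feas[i]:
        return f"species_{j + 1}_wins", (j,)
    ii, jj = inv[i, j], inv[j, i]  # i invades resident j, j invades resident i
    if ii and jj:
        return "coexistence", (i, j)
    if ii and not jj:
        return f"species_{i + 1}_wins", (i,)
    if jj and not ii:
        return f"species_{j + 1}_wins", (j,)
    return "priority_effect", (i, j)


def classify_supply_point(
    config: FoodWebConfig,
    options: SolverOptions | None = None,
    assembly_check: bool = True,
) -> SupplyPointOutcome:
    """Classify the competitive outcome at the config's supply point.

    Pairwise mutual-invasibility logic for up to three consumer species; for
    three species a full-community assembly simulation confirms candidate
    triple coexistence (pairwise invasibility alone does not guarantee it).
    """
    options = options or SolverOptions()
    n = config.n_species
    if n > 3:
        raise ValueError("classification implemented for at most 3 consumer species")

    feas = np.zeros(n, dtype=bool)
    residents: list[EquilibriumResult | None] = [None] * n
    for i in range(n):
        residents[i] = single_resident_equilibrium(config, i, options)
        feas[i] = residents[i] is not None

    inv = np.zeros((n, n), dtype=bool)
    for j in range(n):
        if residents[j] is None:
            continue
        for i in range(n):
            if i == j:
                continue
            inv[i, j] = (
                invasion_growth_rate(config.species[i], residents[j]) > 0
            )

    if not feas.any():
        return SupplyPointOutcome("none", (), inv)

    if n == 1:
        return SupplyPointOutcome("species_1_wins", (0,), inv)

    if n == 2:
        label, detail = _pair_label(0, 1, feas, inv)
        return SupplyPointOutcome(label, detail, inv)

    # n == 3: pairwise structure plus assembly confirmation
    pairs = [(0, 1), (0, 2), (1, 2)]
    mutual = [p for p in pairs if feas[p[0]] and feas[p[1]] and inv[p[0], p[1]] and inv[p[1], p[0]]]
    if assembly_check and len(mutual) >= 2:
        eq = find_equilibrium(config, options=options)
        if eq.converged or eq.oscillatory:
            surv = eq.survivors
            if len(surv) >= 2:
                return SupplyPointOutcome("coexistence", surv, inv)
            if len(surv) == 1:
                return SupplyPointOutcome(f"species_{surv[0] + 1}_wins", surv, inv)
            return SupplyPointOutcome("none", (), inv)
    if mutual:
        return SupplyPointOutcome("coexistence", mutual[0], inv)
    # no mutually invasible pair: reduce to the strongest pairwise outcome
    alive = [i for i in range(3) if feas[i]]
    if len(alive) == 1:
        return SupplyPointOutcome(f"species_{alive[0] + 1}_wins", (alive[0],), inv)
    # winners: species invading every other feasible resident while resisting all
    for i in alive:
        others = [j for j in alive if j != i]
        if all(inv[i, j] for j in others) and not any(inv[j, i] for j in others):
            return SupplyPointOutcome(f"species_{i + 1}_wins", (i,), inv)
    return SupplyPointOutcome("priority_effect", tuple(alive), inv)


def invasion_boundary(
    config: FoodWebConfig,
    invader: int,
    resident: int,
    axis: int = 0,
    bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-10,
    options: SolverOptions | None = None,
) -> float:
    """Supply value on the given axis at which the invader's growth rate
    crosses zero against the resident's equilibrium (bisection root).
    """
    options = options or SolverOptions()

    def G_of(sval: float) -> float:
        s = config.environment.s.copy()
        s[axis] = sval
        cfg = config.with_supply(s)
        eq = single_resident_equilibrium(cfg, resident, options)
        if eq is None:
            # resident infeasible: invader sees the empty environment
            return float(config.species[invader].mu @ s - config.species[invader].m)
        return invasion_growth_rate(config.species[invader], eq)

    g_lo, g_hi = G_of(bracket[0]), G_of(bracket[1])
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"no sign change of invasion growth across bracket {bracket}: "
            f"G({bracket[0]:g})={g_lo:.3g}, G({bracket[1]:g})={g_hi:.3g}"
        )
    return float(brentq(G_of, bracket[0], bracket[1], xtol=tol, rtol=1e-15))


# --------------------------------------------------------------------------
# Coexistence maps


@dataclass
class CoexistenceMap:
    """Grid over supply space with a categorical outcome per cell."""

    s1_grid: np.ndarray
    s2_grid: np.ndarray | None
    outcomes: np.ndarray  # object array of SupplyPointOutcome, shape (n1,) or (n1, n2)
    config: FoodWebConfig

    def labels(self) -> np.ndarray:
        get = np.vectorize(lambda o: o.label, otypes=[object])
        return get(self.outcomes)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels() == label))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        if self.s2_grid is None:
            for i, s1 in enumerate(self.s1_grid):
                o = self.outcomes[i]
                rows.append({"s1": s1, "label": o.label,
                             "survivors": ";".join(str(d + 1) for d in o.detail)})
        else:
            for i, s1 in enumerate(self.s1_grid):
                for j, s2 in enumerate(self.s2_grid):
                    o = self.outcomes[i, j]
                    rows.append({"s1": s1, "s2": s2, "label": o.label,
                                 "survivors": ";".join(str(d + 1) for d in o.detail)})
        return pd.DataFrame(rows)


def coexistence_map(
    config: FoodWebConfig,
    s1_grid: Sequence[float],
    s2_grid: Sequence[float] | None = None,
    options: SolverOptions | None = None,
    assembly_check: bool = True,
) -> CoexistenceMap:
    """Classify every point of a supply grid (2D for two resources, 1D for one).

    Cells where classification fails are labelled ``unknown`` rather than
    aborting the map.
    """
    options = options or SolverOptions()
    s1_grid = np.asarray(s1_grid, dtype=float)
    if np.any(np.diff(s1_grid) <= 0):
        raise ValueError("s1 grid must be strictly increasing")

    def classify(svec) -> SupplyPointOutcome:
        try:
            return classify_supply_point(
                config.with_supply(svec), options, assembly_check=assembly_check
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            return SupplyPointOutcome("unknown", (), None)

    if s2_grid is None:
        if config.n_resources != 1:
            raise ValueError("1D map requires a single-resource config")
        outcomes = np.empty(len(s1_grid), dtype=object)
        for i, s1 in enumerate(s1_grid):
            outcomes[i] = classify([s1])
        return CoexistenceMap(s1_grid, None, outcomes, config)

    s2_grid = np.asarray(s2_grid, dtype=float)
    if np.any(np.diff(s2_grid) <= 0):
        raise ValueError("s2 grid must be strictly increasing")
    if config.n_resources != 2:
        raise ValueError("2D map requires a two-resource config")
    outcomes = np.empty((len(s1_grid), len(s2_grid)), dtype=object)
    for i, s1 in enumerate(s1_grid):
        for j, s2 in enumerate(s2_grid):
            outcomes[i, j] = classify([s1, s2])
    return CoexistenceMap(s1_grid, s2_grid, outcomes, config)


# --------------------------------------------------------------------------
# Diamond-web analytic thresholds


def diamond_thresholds(config: FoodWebConfig) -> tuple[float, float]:
    """Critical supply concentrations (s21, s12) bounding diamond-web coexistence.

    Derived from the single-resident equilibrium with the shared predator
    (resident prey pinned at the predator's subsistence density N = mp/f,
    supply balance s = R * (1 + V*mp/(a*f))) and the invader's zero-growth
    condition.  Coexistence holds for s21 < s < s12; increasing mq lowers
    s21 and raises s12, widening the interval.  mq = 0 recovers the classic
    resource-competition special case.
    """
    if config.n_species != 2 or config.n_resources != 1 or config.n_predators != 1:
        raise ConfigError("diamond web requires exactly 2 species, 1 resource, 1 predator")
    sp1, sp2 = config.species
    pr = config.predators[0]
    mu1, mu2 = float(sp1.mu[0]), float(sp2.mu[0])
    V1, V2 = float(sp1.V[0]), float(sp2.V[0])
    g1, g2 = float(sp1.g[0]), float(sp2.g[0])
    f1, f2 = float(pr.f[0]), float(pr.f[1])
    mp, a = pr.mp, config.environment.a
    if abs(sp1.m - sp2.m) > 1e-12 or abs(sp1.mq - sp2.mq) > 1e-12:
        raise ConfigError("thresholds assume community-uniform m and mq")
    m, mq = sp1.m, sp1.mq
    if not mu1 > mu2:
        raise ConfigError("stability ordering violated: requires mu1 > mu2")
    if g1 < g2:
        raise ConfigError("stability ordering violated: requires g1 > g2")
    if f1 <= 0 or f2 <= 0:
        raise ConfigError("predator must assimilate both prey (f1, f2 > 0)")
    D = g1 * mu2 - g2 * mu1
    num21 = (g1 - g2) * m - mq * mp * g2 / f1
    num12 = (g1 - g2) * m + mq * mp * g1 / f2
    if D <= 0:
        if num21 == 0 and num12 == 0:
            return 0.0, 0.0  # no trait trade-off: degenerate thresholds
        raise ConfigError(
            "trade-off condition violated: requires g1*mu2 - g2*mu1 > 0"
        )
    s21 = num21 / D * (1.0 + V1 * mp / (a * f1))
    s12 = num12 / D * (1.0 + V2 * mp / (a * f2))
    return float(s21), float(s12)
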