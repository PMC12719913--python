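"""Many-species communities with trait trade-offs and productivity-diversity
relationship (PDR) sweeps.

Communities are generated along a gleaner-defender trade-off: intrinsic
growth rates mu_i are evenly spaced and decreasing, vulnerability to
predation follows a power law g_i = c * mu_i**beta with beta > 1, so that
fast growers are poorly defended (mu_i decreasing, mu_i/g_i increasing).
Predator diets are contiguous windows over the trait-ranked prey; one
predator covering all prey is the diamond-web limit, one predator per prey
is fully specialist predation.  Richness is recorded along a supply
gradient and the resulting curve is classified by quadratic regression into
the standard PDR shape taxonomy: Concave- (unimodal), Concave+
(anti-unimodal), Linear+/Linear- and NS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dynamics import SolverOptions, find_equilibrium
from .foodweb import (
    FoodWebConfig,
    PredatorTraits,
    ResourceEnvironment,
    SpeciesTraits,
)

__all__ = [
    "TraitGenSpec",
    "DietStructure",
    "PDRCurve",
    "PDRLabel",
    "generate_bottom_up_traits",
    "generate_diamond_traits",
    "generate_predator_diets",
    "build_community",
    "pdr_sweep",
    "classify_pdr",
    "pdr_experiment",
]


@dataclass
class TraitGenSpec:
    """Generator settings for trade-off-structured communities.

    mu values are evenly spaced, decreasing over ``mu_range``; consumption is
    tied to growth through a fixed yield (V_i = mu_i / yield_Y); vulnerability
    is g_i = c * mu_i**tradeoff_exponent (exponent > 1 enforces the
    gleaner-defender ordering); predator assimilation is f_i = gamma * g_i.
    All rates are per unit time; concentrations in arbitrary units.
    """

    n_species: int = 100
    mu_range: tuple[float, float] = (0.5, 2.0)
    tradeoff_exponent: float = 2.0
    c: float = 1.6
    yield_Y: float = 0.3
    gamma: float = 2.0 / 3.0
    m: float = 0.1
    mq: float = 0.01
    mp: float = 0.1
    a: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mu_range
        if not (hi > lo > 0):
            raise ValueError("mu_range must satisfy mu_max > mu_min > 0")
        if not self.tradeoff_exponent > 1:
            raise ValueError(
                "tradeoff_exponent must exceed 1 (beta > 1 makes mu/g increase "
                "as mu decreases, the gleaner-defender ordering)"
            )
        if self.n_species < 1:
            raise ValueError("n_species must be positive")

    def mu_values(self) -> np.ndarray:
        lo, hi = self.mu_range
        if self.n_species == 1:
            return np.array([hi])
        return np.linspace(hi, lo, self.n_species)


def generate_bottom_up_traits(spec: TraitGenSpec, s: float = 1.0) -> FoodWebConfig:
    """Predator-free guild on one shared resource, mu strictly decreasing."""
    mu = spec.mu_values()
    species = [
        SpeciesTraits(
            mu=[float(mui)],
            V=[float(mui / spec.yield_Y)],
            g=np.zeros(0),
            m=spec.m,
            mq=spec.mq,
        )
        for mui in mu
    ]
    env = ResourceEnvironment(s=[s], a=spec.a)
    return FoodWebConfig(species, [], env).require_valid()


def generate_diamond_traits(spec: TraitGenSpec, s: float = 1.0) -> FoodWebConfig:
    """Many-prey diamond web: one resource, one shared predator, g = c*mu**beta."""
    mu = spec.mu_values()
    g = spec.c * mu ** spec.tradeoff_exponent
    if spec.n_species > 1:
        ratio = mu / g
        assert np.all(np.diff(mu) < 0) and np.all(np.diff(ratio) > 0), (
            "trade-off orderings violated (should be impossible for beta > 1)"
        )
    species = [
        SpeciesTraits(
            mu=[float(mui)],
            V=[float(mui / spec.yield_Y)],
            g=[float(gi)],
            m=spec.m,
            mq=spec.mq,
        )
        for mui, gi in zip(mu, g)
    ]
    predator = PredatorTraits(f=spec.gamma * g, mp=spec.mp)
    env = ResourceEnvironment(s=[s], a=spec.a)
    return FoodWebConfig(species, [predator], env).require_valid()


@dataclass
class DietStructure:
    """Per-predator prey windows over trait-ranked prey (0-based indices)."""

    n_prey: int
    windows: list[tuple[int, ...]] = field(default_factory=list)
    overlap: int = 0

    @property
    def n_predators(self) -> int:
        return len(self.windows)

    def covers_all(self) -> bool:
        covered = set().union(*map(set, self.windows)) if self.windows else set()
        return covered == set(range(self.n_prey)) or self.n_predators == 0


def generate_predator_diets(
    n_prey: int, n_predators: int, overlap: int = 0
) -> DietStructure:
    """Contiguous diet windows of width ceil(n_prey/n_predators) + overlap.

    Window starts are spread evenly over the trait-ranked prey; windows
    truncate at the last prey (the trade-off extremes never share a
    predator).  n_predators = n_prey with overlap 0 gives one-to-one
    specialist predation; n_predators = 0 is the pure bottom-up guild.
    """
    if not (0 <= n_predators <= n_prey):
        raise ValueError("need 0 <= n_predators <= n_prey")
    if overlap < 0:
        raise ValueError("overlap must be nonnegative")
    if n_predators == 0:
        return DietStructure(n_prey=n_prey, windows=[], overlap=overlap)
    width = math.ceil(n_prey / n_predators) + overlap
    windows = []
    for h in range(n_predators):
        start = (h * n_prey) // n_predators
        windows.append(tuple(range(start, min(start + width, n_prey))))
    for w1, w2 in zip(windows[:-1], windows[1:]):
        if set(w1) == set(w2):
            raise ValueError(
                "overlap too large: adjacent diet windows collapse to the same prey set"
            )
    ds = DietStructure(n_prey=n_prey, windows=windows, overlap=overlap)
    assert ds.covers_all()
    return ds


def build_community(
    spec: TraitGenSpec, diets: DietStructure, s: float = 1.0
) -> FoodWebConfig:
    """Assemble a multi-predator web from the trait trade-off and a diet structure.

    Prey i is vulnerable (g_hi = c * mu_i**beta) to every predator whose diet
    window contains it; each predator assimilates its diet at f = gamma * g.
    """
    if diets.n_prey != spec.n_species:
        raise ValueError("diet structure and trait spec disagree on prey count")
    if diets.n_predators == 0:
        return generate_bottom_up_traits(spec, s=s)
    mu = spec.mu_values()
    g_scalar = spec.c * mu ** spec.tradeoff_exponent
    l = diets.n_predators
    membership = np.zeros((spec.n_species, l))
    for h, win in enumerate(diets.windows):
        membership[list(win), h] = 1.0
    species = [
        SpeciesTraits(
            mu=[float(mu[i])],
            V=[float(mu[i] / spec.yield_Y)],
            g=g_scalar[i] * membership[i],
            m=spec.m,
            mq=spec.mq,
        )
        for i in range(spec.n_species)
    ]
    predators = [
        PredatorTraits(f=spec.gamma * g_scalar * membership[:, h], mp=spec.mp)
        for h in range(l)
    ]
    env = ResourceEnvironment(s=[s], a=spec.a)
    return FoodWebConfig(species, predators, env).require_valid()


@dataclass
class PDRCurve:
    """Richness along a supply gradient, with optional shape classification."""

    s_grid: np.ndarray
    richness: np.ndarray  # float array; NaN marks convergence failures
    config_id: str = ""
    classification: "PDRLabel | None" = None
    survivor_sets: list[tuple[int, ...]] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s_grid, "richness": self.richness})


@dataclass
class PDRLabel:
    """PDR shape category with the fitted quadratic evidence behind it."""

    label: str  # Concave- | Concave+ | Linear+ | Linear- | NS
    coefficients: dict[str, float]
    p_values: dict[str, float]
    peak_interior: bool
    degenerate: bool = False


def default_supply_grid(n_points: int = 40, lo: float = 0.01, hi: float = 100.0) -> np.ndarray:
    """Log-spaced supply gradient wide enough to expose both PDR limbs."""
    return np.geomspace(lo, hi, n_points)


def pdr_sweep(
    template: FoodWebConfig,
    s_grid: np.ndarray,
    options: SolverOptions | None = None,
    config_id: str = "",
) -> PDRCurve:
    """Assemble and equilibrate the community at each supply value; record richness.

    Each point starts from the common simultaneous-introduction initial
    condition.  Non-converging points are recorded as NaN, never fabricated.
    """
    options = options or SolverOptions()
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("supply grid must be strictly increasing")
    rich = np.full(len(s_grid), np.nan)
    sets: list[tuple[int, ...]] = []
    for i, s in enumerate(s_grid):
        cfg = template.with_supply([s])
        try:
            eq = find_equilibrium(cfg, options=options)
        except RuntimeError:
            sets.append(())
            continue
        if eq.converged or eq.oscillatory:
            rich[i] = len(eq.survivors)
            sets.append(eq.survivors)
        else:
            sets.append(())
    return PDRCurve(s_grid=s_grid, richness=rich, config_id=config_id, survivor_sets=sets)


def classify_pdr(curve: PDRCurve, alpha: float = 0.05) -> PDRLabel:
    """Classify a PDR curve by OLS of richness on standardized log-supply.

    Concave- / Concave+ require a significant quadratic term with the fitted
    extremum interior to the observed range; otherwise a significant linear
    term gives Linear+/Linear-; otherwise NS.
    """
    ok = np.isfinite(curve.richness)
    if ok.sum() < 5:
        raise ValueError("need at least 5 supply points with defined richness")
    y = curve.richness[ok]
    z_raw = np.log10(curve.s_grid[ok])
    if np.ptp(y) == 0:
        return PDRLabel(
            label="NS", coefficients={}, p_values={}, peak_interior=False,
            degenerate=True,
        )
    z = (z_raw - z_raw.mean()) / z_raw.std()
    X = sm.add_constant(np.column_stack([z, z**2]))
    fit = sm.OLS(y, X).fit()
    b0, b1, b2 = fit.params
    p0, p1, p2 = fit.pvalues
    coefficients = {"const": float(b0), "linear": float(b1), "quadratic": float(b2)}
    p_values = {"const": float(p0), "linear": float(p1), "quadratic": float(p2)}
    peak = -b1 / (2 * b2) if b2 != 0 else np.inf
    interior = bool(z.min() < peak < z.max())
    # a fitted extremum must be empirically supported: the observed extreme
    # value has to fall strictly inside the gradient and beat both endpoints
    # (a monotone convex/concave curve is a trend, not a hump)
    imax, imin = int(np.argmax(y)), int(np.argmin(y))
    hump = 0 < imax < len(y) - 1 and y[imax] > y[0] and y[imax] > y[-1]
    dip = 0 < imin < len(y) - 1 and y[imin] < y[0] and y[imin] < y[-1]
    if p2 < alpha and b2 < 0 and interior and hump:
        return PDRLabel("Concave-", coefficients, p_values, peak_interior=True)
    if p2 < alpha and b2 > 0 and interior and dip:
        return PDRLabel("Concave+", coefficients, p_values, peak_interior=True)
    # fall back to the linear trend (refit without the quadratic term)
    Xl = sm.add_constant(z)
    lfit = sm.OLS(y, Xl).fit()
    coefficients["linear"] = float(lfit.params[1])
    p_values["linear"] = float(lfit.pvalues[1])
    if lfit.pvalues[1] < alpha:
        label = "Linear+" if lfit.params[1] > 0 else "Linear-"
        return PDRLabel(label, coefficients, p_values, peak_interior=interior)
    return PDRLabel("NS", coefficients, p_values, peak_interior=interior)


def pdr_experiment(
    n_prey: int,
    nop_list: list[int],
    spec: TraitGenSpec | None = None,
    s_grid: np.ndarray | None = None,
    options: SolverOptions | None = None,
    overlap: int = 0,
    alpha: float = 0.05,
) -> dict[int, PDRCurve]:
    """One PDR curve per predator count (NOP), sharing a single trait draw.

    Curves differ only in diet structure, isolating the effect of predator
    specialisation (apparent-competition strength) on the PDR shape.
    """
    spec = spec or TraitGenSpec(n_species=n_prey)
    if spec.n_species != n_prey:
        raise ValueError("spec.n_species must equal n_prey")
    s_grid = default_supply_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    options = options or SolverOptions()
    out: dict[int, PDRCurve] = {}
    for nop in nop_list:
        diets = generate_predator_diets(n_prey, nop, overlap=overlap)
        template = build_community(spec, diets)
        curve = pdr_sweep(template, s_grid, options, config_id=f"nop={nop}")
        try:
            curve.classification = classify_pdr(curve, alpha=alpha)
        except ValueError:
            curve.classification = None
        out[nop] = curve
    return out
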