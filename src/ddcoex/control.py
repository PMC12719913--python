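"""Analytical steady-state abundance predictions ("control formulas").

At a static equilibrium with quadratic density dependence each coexisting
species satisfies

    N_hat_i = N_bar + (G_i - G_bar) / mq

where G_i is its invasion growth rate at the equilibrium resource/predator
levels, G_bar is a community-average growth rate weighted by the shared
limiting factor, and N_bar is the mean density set by that factor:

* bottom-up guild (one shared resource): N_bar = a(s - R_hat) / (sum_j V_j R_hat),
  weights V_j (resource uptake);
* top-down guild (one shared predator): N_bar = mp / sum_j f_j (the predator's
  subsistence prey density), weights f_j (predator assimilation).

Sums run over the realized surviving set: the guild formulas iteratively drop
species with non-positive predicted density and re-solve until the set is
stable.  In the mq -> 0 limit the formulas degenerate (coexistence then
requires G_i = G_bar for all i), and the functions raise rather than return
infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foodweb import FoodWebConfig, SpeciesTraits

__all__ = [
    "ControlPrediction",
    "general_control",
    "bottom_up_control",
    "top_down_control",
    "direct_density",
    "bottom_up_equilibrium",
    "top_down_equilibrium",
]


@dataclass
class ControlPrediction:
    """Predicted guild equilibrium: densities, growth rates, and weights.

    ``N_hat`` and ``G`` are full-length (one entry per species in the pool);
    species outside the surviving set carry N_hat = 0.  ``survivors`` lists
    the indices over which the weighted sums run.
    """

    N_hat: np.ndarray
    N_bar: float
    G: np.ndarray
    G_bar: float
    weights: np.ndarray
    survivors: tuple[int, ...]

    def weighted_mean_density(self) -> float:
        """Identity check: sum_j w_j N_hat_j / sum_j w_j (== N_bar)."""
        w = self.weights[list(self.survivors)]
        n = self.N_hat[list(self.survivors)]
        return float(w @ n / w.sum())


def general_control(
    N_bar: float, G: np.ndarray, G_bar: float, mq: float
) -> np.ndarray:
    """General control formula N_hat_i = N_bar + (G_i - G_bar)/mq.

    Negative entries signal infeasibility of the assumed coexisting set (the
    species cannot be part of it), not a clipped density.
    """
    if mq <= 0:
        raise ValueError(
            "control formula requires mq > 0; in the mq = 0 limit coexistence "
            "requires equal invasion growth rates (classic resource competition)"
        )
    G = np.asarray(G, dtype=float)
    return N_bar + (G - G_bar) / mq


def _uniform_mq(config: FoodWebConfig, subset) -> float:
    mqs = {config.species[i].mq for i in subset}
    xs = {config.species[i].x for i in subset}
    if len(mqs) != 1:
        raise ValueError("guild control formulas assume a community-uniform mq")
    if xs != {2.0}:
        raise ValueError("guild control formulas are derived for quadratic mortality (x = 2)")
    (mq,) = mqs
    if mq <= 0:
        raise ValueError(
            "control formula requires mq > 0; in the mq = 0 limit coexistence "
            "requires equal invasion growth rates (classic resource competition)"
        )
    return mq


def _iterate_guild(
    G: np.ndarray,
    weights: np.ndarray,
    n_bar_of: "callable",
    mq: float,
    candidates: np.ndarray,
) -> ControlPrediction:
    """Predict, drop non-positive-density species, re-predict to a fixed point."""
    active = list(candidates)
    n = len(G)
    for _ in range(n + 1):
        w = weights[active]
        if w.sum() <= 0:
            raise ValueError("surviving set has zero total weight")
        N_bar = n_bar_of(active)
        G_bar = float(w @ G[active] / w.sum())
        N_act = general_control(N_bar, G[active], G_bar, mq)
        if np.all(N_act > 0):
            N_hat = np.zeros(n)
            N_hat[active] = N_act
            return ControlPrediction(
                N_hat=N_hat,
                N_bar=float(N_bar),
                G=G,
                G_bar=G_bar,
                weights=weights,
                survivors=tuple(active),
            )
        active = [i for i, Ni in zip(active, N_act) if Ni > 0]
        if not active:
            return ControlPrediction(
                N_hat=np.zeros(n), N_bar=0.0, G=G, G_bar=0.0,
                weights=weights, survivors=(),
            )
    raise RuntimeError("survivor-set iteration failed to reach a fixed point")


def bottom_up_control(
    config: FoodWebConfig,
    R_hat: float,
    P_hat: np.ndarray | None = None,
    candidates=None,
) -> ControlPrediction:
    """Bottom-up guild prediction at the shared-resource level ``R_hat``.

    G_i = mu_i R_hat - m - sum_h g_hi P_hat_h; N_bar is the resource flux
    a (s - R_hat) divided by the surviving guild's total uptake rate
    sum_j V_j R_hat; weights are the uptake rates V_j.
    """
    if config.n_resources != 1:
        raise ValueError("bottom-up guild formula requires a single shared resource")
    arr = config.arrays()
    s = float(arr.s[0])
    a = arr.a
    R_hat = float(R_hat)
    if not (0 < R_hat <= s):
        raise ValueError(f"invalid equilibrium resource level R_hat={R_hat:g} (supply s={s:g})")
    P_hat = np.zeros(arr.l) if P_hat is None else np.asarray(P_hat, dtype=float)
    candidates = np.arange(arr.n) if candidates is None else np.asarray(candidates)
    mq = _uniform_mq(config, candidates)
    G = arr.MU[:, 0] * R_hat - arr.m - arr.Gm @ P_hat
    V = arr.Vm[:, 0]
    if np.any(V[candidates] <= 0):
        raise ValueError("all guild members must consume the shared resource (V > 0)")

    def n_bar_of(active):
        return a * (s - R_hat) / (V[active].sum() * R_hat)

    return _iterate_guild(G, V, n_bar_of, mq, candidates)


def top_down_control(
    config: FoodWebConfig,
    R: np.ndarray | float,
    P_hat: float,
    candidates=None,
) -> ControlPrediction:
    """Top-down guild prediction at resource levels ``R`` and predator ``P_hat``.

    G_i = sum_h mu_ih R_h - g_i P_hat - m; N_bar = mp / sum_j f_j is the
    predator's subsistence prey density; weights are the assimilation rates f_j.
    """
    if config.n_predators != 1:
        raise ValueError("top-down guild formula requires a single shared predator")
    arr = config.arrays()
    R = np.atleast_1d(np.asarray(R, dtype=float))
    candidates = np.arange(arr.n) if candidates is None else np.asarray(candidates)
    mq = _uniform_mq(config, candidates)
    f = arr.F[0]
    if f[candidates].sum() <= 0:
        raise ValueError("predator assimilation rates sum to zero over the guild")
    G = arr.MU @ R - arr.m - arr.Gm[:, 0] * float(P_hat)
    mp = float(arr.mp[0])

    def n_bar_of(active):
        return mp / f[active].sum()

    return _iterate_guild(G, f, n_bar_of, mq, candidates)


def direct_density(
    species: SpeciesTraits,
    R: np.ndarray | float,
    P: np.ndarray | float = (),
) -> float:
    """Pointwise equilibrium density N = (G/mq)^(1/(x-1)), clipped at 0.

    G = sum_h mu_h R_h - m - sum_h g_h P_h; with quadratic mortality (x=2)
    this is G/mq.  Doubling mq halves the density at fixed G.
    """
    if species.mq <= 0:
        raise ValueError("direct density evaluation requires mq > 0")
    R = np.atleast_1d(np.asarray(R, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float)) if np.size(P) else np.zeros(0)
    G = float(species.mu @ R - species.m)
    if len(P):
        G -= float(species.g[: len(P)] @ P)
    if G <= 0:
        return 0.0
    return float((G / species.mq) ** (1.0 / (species.x - 1.0)))


# --------------------------------------------------------------------------
# Self-consistent guild equilibria (no simulation input required)


def bottom_up_equilibrium(config: FoodWebConfig) -> tuple[float, ControlPrediction]:
    """Solve the predator-free bottom-up guild equilibrium from scratch.

    Finds the shared-resource level R_hat at which the resource balance
    a(s - R) = sum_i V_i N_i(R) R closes with N_i(R) = max(mu_i R - m, 0)/mq,
    then returns the control-formula prediction there.
    """
    from scipy.optimize import brentq

    if config.n_resources != 1 or config.n_predators != 0:
        raise ValueError("requires a predator-free single-resource guild")
    arr = config.arrays()
    _uniform_mq(config, range(arr.n))
    mq = config.species[0].mq
    s, a = float(arr.s[0]), arr.a
    mu, V, m = arr.MU[:, 0], arr.Vm[:, 0], arr.m

    def balance(R: float) -> float:
        N = np.maximum(mu * R - m, 0.0) / mq
        return a * (s - R) - float(V @ N) * R

    if balance(s) >= 0:  # nobody can grow: resources sit at supply
        pred = ControlPrediction(
            N_hat=np.zeros(arr.n), N_bar=0.0, G=mu * s - m, G_bar=0.0,
            weights=V, survivors=(),
        )
        return s, pred
    R_hat = float(brentq(balance, 0.0, s, xtol=1e-15, rtol=1e-15))
    return R_hat, bottom_up_control(config, R_hat)


def top_down_equilibrium(
    config: FoodWebConfig, R: np.ndarray | float | None = None
) -> tuple[float, ControlPrediction]:
    """Solve the top-down guild equilibrium from scratch at fixed resources.

    With resources pinned (non-constraining), the predator level satisfies
    sum_i f_i G_i(P) = mq * mp over the surviving set; solved by linear
    elimination with iterative removal of infeasible species.
    """
    if config.n_predators != 1:
        raise ValueError("requires a single shared predator")
    arr = config.arrays()
    R = arr.s.copy() if R is None else np.atleast_1d(np.asarray(R, dtype=float))
    mq = _uniform_mq(config, range(arr.n))
    f = arr.F[0]
    g = arr.Gm[:, 0]
    base = arr.MU @ R - arr.m  # growth with no predation
    mp = float(arr.mp[0])

    active = list(np.flatnonzero(f > 0))
    for _ in range(arr.n + 1):
        fs = f[active]
        denom = float(fs @ g[active])
        if denom <= 0:
            raise ValueError("guild is not predator-regulated (sum f_i g_i = 0)")
        P = (float(fs @ base[active]) - mq * mp) / denom
        N = (base - g * P) / mq
        bad = [i for i in active if N[i] <= 0]
        if not bad:
            if P <= 0:
                raise ValueError("predator cannot persist on this guild (P <= 0)")
            return float(P), top_down_control(config, R, P, candidates=active)
        active = [i for i in active if N[i] > 0]
        if not active:
            raise ValueError("no species sustains the predator at these resources")
    raise RuntimeError("survivor-set iteration failed to reach a fixed point")
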