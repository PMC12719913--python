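"""Integrate communities to equilibrium and extract survivor sets.

Equilibration integrates population densities in log space (resources stay
linear), which tracks the very deep transient troughs of predator-prey
oscillations exactly instead of truncating them at the integrator's absolute
tolerance; a population only goes extinct when its log-density underflows
(it then stays at zero, which is absorbing).  Once the max-norm
per-capita residual of the extant community is small, the state is polished
with a Newton root solve restricted to the extant sub-community, which
drives the residual to machine precision and closes the resource mass
balance; species below the extinction threshold are zeroed by the polish.
If the horizon (with one automatic doubling) is exhausted without
convergence, a trailing window is inspected for sustained oscillation and,
if found, window-averaged densities are reported (cycle-averaged
equilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .foodweb import CommunityState, FoodWebConfig, WebArrays

__all__ = [
    "SolverOptions",
    "Trajectory",
    "EquilibriumResult",
    "IntegrationError",
    "default_initial_state",
    "simulate",
    "find_equilibrium",
    "richness",
]

class IntegrationError(RuntimeError):
    """Integration failure; carries the last good state."""

    def __init__(self, message: str, last_state: CommunityState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class SolverOptions:
    """Numerical controls for simulation and equilibrium detection.

    extinction_threshold is the density below which a species is reported
    absent from the survivor set; equilibrium_tol bounds the max-norm
    per-capita residual; window is the trailing fraction of the horizon used
    for oscillation detection and cycle averaging.
    """

    t_max: float = 1e4
    rtol: float = 1e-8
    atol: float = 1e-10
    extinction_threshold: float = 1e-6
    equilibrium_tol: float = 1e-8
    window: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_max <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("t_max, rtol, atol must be positive")
        if not (0 < self.window < 1):
            raise ValueError("window must be a fraction in (0, 1)")
        if self.extinction_threshold <= 0 or self.equilibrium_tol <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Trajectory:
    """Time-ordered community states from one integration."""

    t: np.ndarray
    N: np.ndarray  # (m, n)
    P: np.ndarray  # (m, l)
    R: np.ndarray  # (m, k)

    def final_state(self) -> CommunityState:
        return CommunityState(self.N[-1], self.P[-1], self.R[-1], t=float(self.t[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.t}
        for i in range(self.N.shape[1]):
            cols[f"N_{i + 1}"] = self.N[:, i]
        for h in range(self.P.shape[1]):
            cols[f"P_{h + 1}"] = self.P[:, h]
        for j in range(self.R.shape[1]):
            cols[f"R_{j + 1}"] = self.R[:, j]
        return pd.DataFrame(cols)


@dataclass
class EquilibriumResult:
    """Converged (or cycle-averaged) community state with diagnostics."""

    state: CommunityState
    survivors: tuple[int, ...]
    predator_survivors: tuple[int, ...]
    converged: bool
    oscillatory: bool
    residual: float
    t_end: float
    extinction_threshold: float = 1e-6

    @property
    def richness(self) -> int:
        return len(self.survivors)

    def to_dict(self) -> dict:
        return {
            "N": self.state.N.tolist(),
            "P": self.state.P.tolist(),
            "R": self.state.R.tolist(),
            "survivors": list(self.survivors),
            "predator_survivors": list(self.predator_survivors),
            "converged": self.converged,
            "oscillatory": self.oscillatory,
            "residual": self.residual,
            "t_end": self.t_end,
            "extinction_threshold": self.extinction_threshold,
        }


def default_initial_state(
    config: FoodWebConfig, n0: float = 1e-3, p0: float = 1e-3
) -> CommunityState:
    """Simultaneous-introduction assembly init: all species rare, R at supply."""
    return CommunityState(
        N=np.full(config.n_species, n0),
        P=np.full(config.n_predators, p0),
        R=config.environment.s.copy(),
    )


# --------------------------------------------------------------------------
# residual / polish helpers (linear space)


def _residual(arr: WebArrays, y: np.ndarray, thr: float) -> float:
    """Max-norm residual: per-capita rates of extant populations, scaled dR."""
    N, P, R = arr.unpack(y)
    parts = [0.0]
    act_n = N > thr
    if act_n.any():
        parts.append(np.max(np.abs(arr.per_capita_growth(N, P, R)[act_n])))
    act_p = P > thr
    if act_p.any():
        parts.append(np.max(np.abs(arr.predator_per_capita(N)[act_p])))
    if not arr.fixed and arr.k:
        scale = np.maximum(arr.a * np.maximum(arr.s, 1e-12), 1e-12)
        parts.append(np.max(np.abs(arr.resource_rate(N, R)) / scale))
    return float(max(parts))


def _polish(
    arr: WebArrays,
    y: np.ndarray,
    thr: float,
    act_n: np.ndarray | None = None,
    act_p: np.ndarray | None = None,
    rel_guard: float = 0.5,
) -> np.ndarray | None:
    """Newton-polish the extant sub-community to a true root of the dynamics.

    Populations outside the active sets (default: above the extinction
    threshold) are zeroed; the remaining densities and the free resources
    are solved to machine precision.  Returns None if the root solve fails,
    goes negative, or wanders further than ``rel_guard`` relative change.
    """
    N, P, R = arr.unpack(y)
    act_n = np.flatnonzero(N > thr) if act_n is None else act_n
    act_p = np.flatnonzero(P > thr) if act_p is None else act_p
    free_R = not arr.fixed and arr.k > 0

    def split(x):
        Nf = np.zeros(arr.n)
        Pf = np.zeros(arr.l)
        Nf[act_n] = x[: len(act_n)]
        Pf[act_p] = x[len(act_n) : len(act_n) + len(act_p)]
        Rf = x[len(act_n) + len(act_p) :] if free_R else R
        return Nf, Pf, Rf

    def fun(x):
        Nf, Pf, Rf = split(x)
        eqs = []
        if len(act_n):
            eqs.append(arr.per_capita_growth(Nf, Pf, Rf)[act_n])
        if len(act_p):
            eqs.append(arr.predator_per_capita(Nf)[act_p])
        if free_R:
            eqs.append(arr.resource_rate(Nf, Rf))
        return np.concatenate(eqs) if eqs else np.zeros(0)

    x0 = np.concatenate([N[act_n], P[act_p], R if free_R else np.zeros(0)])
    if not len(x0):
        return y if not free_R else arr.pack(np.zeros(arr.n), np.zeros(arr.l), arr.s.copy())
    sol = root(fun, x0, method="hybr")
    if not sol.success or np.any(sol.x < -1e-9):
        return None
    rel = np.abs(sol.x - x0) / np.maximum(np.abs(x0), 1e-12)
    if np.max(rel) > rel_guard:  # solver wandered to a different equilibrium
        return None
    Nf, Pf, Rf = split(np.maximum(sol.x, 0.0))
    return arr.pack(Nf, Pf, Rf)


def _verified_root(
    arr: WebArrays,
    y: np.ndarray,
    thr: float,
    tol: float,
    act_n: np.ndarray,
    act_p: np.ndarray,
) -> np.ndarray | None:
    """Polish onto the equilibrium of the given active sub-community and
    verify it is the trajectory's omega-limit: residual below tolerance,
    locally stable, and no excluded population can invade it."""
    polished = _polish(arr, y, thr, act_n=act_n, act_p=act_p, rel_guard=np.inf)
    if polished is None or _residual(arr, polished, thr) >= tol:
        return None
    Nf, Pf, Rf = arr.unpack(polished)
    if np.any(Nf[act_n] < thr) or (len(act_p) and np.any(Pf[act_p] < thr)):
        return None  # root left the claimed extant set
    excluded_n = np.setdiff1d(np.arange(arr.n), act_n)
    if np.any(arr.invasion_rates(Pf, Rf)[excluded_n] > 1e-10):
        return None
    excluded_p = np.setdiff1d(np.arange(arr.l), act_p)
    if np.any(arr.predator_per_capita(Nf)[excluded_p] > 1e-10):
        return None
    if not _locally_stable(arr, polished, thr):
        return None
    return polished


def _endgame_polish(
    arr: WebArrays, y: np.ndarray, thr: float, tol: float
) -> np.ndarray | None:
    """Resolve a slow assembly endgame directly.

    Near equilibrium the remaining motion is either a marginal species
    growing slowly towards its interior density or a near-neutral loser
    declining slowly towards extinction.  Both are resolved by solving the
    candidate equilibrium and verifying it with ``_verified_root``: first
    with every above-threshold population retained, then with the declining
    ones excluded.
    """
    N, P, R = arr.unpack(y)
    gN = arr.per_capita_growth(N, P, R)
    gP = arr.predator_per_capita(N)
    ext_n, ext_p = np.flatnonzero(N > thr), np.flatnonzero(P > thr)
    out = _verified_root(arr, y, thr, tol, ext_n, ext_p)
    if out is not None:
        return out
    act_n = np.flatnonzero((N > thr) & (gN >= 0))
    act_p = np.flatnonzero((P > thr) & (gP >= 0))
    if len(act_n) < len(ext_n) or len(act_p) < len(ext_p):
        return _verified_root(arr, y, thr, tol, act_n, act_p)
    return None


def _locally_stable(arr: WebArrays, y: np.ndarray, thr: float) -> bool:
    """Local stability of the extant subsystem at an equilibrium point.

    Finite-difference Jacobian of the flow restricted to extant populations
    and free resources; stable when no eigenvalue has a meaningfully positive
    real part.  Used only to tell slow damped ringing apart from a genuine
    limit cycle (which surrounds an unstable interior equilibrium).
    """
    N, P, R = arr.unpack(y)
    act_n = np.flatnonzero(N > thr)
    act_p = np.flatnonzero(P > thr)
    free_R = not arr.fixed and arr.k > 0

    def flow(x):
        Nf = np.zeros(arr.n)
        Pf = np.zeros(arr.l)
        Nf[act_n] = x[: len(act_n)]
        Pf[act_p] = x[len(act_n) : len(act_n) + len(act_p)]
        Rf = x[len(act_n) + len(act_p) :] if free_R else R
        out = [Nf[act_n] * arr.per_capita_growth(Nf, Pf, Rf)[act_n]]
        if len(act_p):
            out.append(Pf[act_p] * arr.predator_per_capita(Nf)[act_p])
        if free_R:
            out.append(arr.resource_rate(Nf, Rf))
        return np.concatenate(out)

    x0 = np.concatenate([N[act_n], P[act_p], R if free_R else np.zeros(0)])
    if not len(x0):
        return True
    J = np.zeros((len(x0), len(x0)))
    for j in range(len(x0)):
        h = 1e-7 * max(abs(x0[j]), 1e-6)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (flow(xp) - flow(xm)) / (2 * h)
    eig = np.linalg.eigvals(J)
    return bool(np.max(eig.real) < 1e-7)


# --------------------------------------------------------------------------
# log-space integration machinery


class _LogSystem:
    """Population dynamics in log-density coordinates over an active set."""

    def __init__(self, arr: WebArrays, active_n: np.ndarray, active_p: np.ndarray):
        self.arr = arr
        self.an = active_n
        self.ap = active_p

    def to_log(self, y: np.ndarray) -> np.ndarray:
        N, P, R = self.arr.unpack(y)
        return np.concatenate([np.log(N[self.an]), np.log(P[self.ap]), R])

    def to_linear(self, yl: np.ndarray) -> np.ndarray:
        arr = self.arr
        nn, pp = len(self.an), len(self.ap)
        N = np.zeros(arr.n)
        P = np.zeros(arr.l)
        N[self.an] = np.exp(np.minimum(yl[:nn], 700.0))
        P[self.ap] = np.exp(np.minimum(yl[nn : nn + pp], 700.0))
        R = np.maximum(yl[nn + pp :], 0.0)
        return arr.pack(N, P, R)

    def ode(self):
        arr, an, ap = self.arr, self.an, self.ap
        nn, pp = len(an), len(ap)

        def f(t, yl):
            N = np.zeros(arr.n)
            P = np.zeros(arr.l)
            N[an] = np.exp(np.minimum(yl[:nn], 700.0))
            P[ap] = np.exp(np.minimum(yl[nn : nn + pp], 700.0))
            R = yl[nn + pp :]
            dz = arr.per_capita_growth(N, P, R)[an]
            dw = arr.predator_per_capita(N)[ap]
            dR = arr.resource_rate(N, R)
            return np.concatenate([dz, dw, dR])

        return f

    def atol(self, options: SolverOptions) -> np.ndarray:
        # absolute tolerance on a log-density is a relative tolerance on the
        # density itself; resources keep the linear atol
        return np.concatenate([
            np.full(len(self.an) + len(self.ap), 1e-8),
            np.full(self.arr.k, options.atol),
        ])


def _integrate_log(sys: _LogSystem, yl, t0, t1, options, t_eval=None):
    sol = solve_ivp(
        sys.ode(),
        (t0, t1),
        yl,
        method="LSODA",
        rtol=options.rtol,
        atol=sys.atol(options),
        t_eval=t_eval,
    )
    if not sol.success:
        y = sys.to_linear(sol.y[:, -1])
        N, P, R = sys.arr.unpack(y)
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.3g}: {sol.message}",
            last_state=CommunityState(N, P, R, t=float(sol.t[-1])),
        )
    return sol


def find_equilibrium(
    config: FoodWebConfig,
    init: CommunityState | None = None,
    options: SolverOptions | None = None,
) -> EquilibriumResult:
    """Integrate until the community reaches a point or cycle-averaged equilibrium.

    Returns a converged point equilibrium (residual < equilibrium_tol), or an
    oscillatory result with trailing-window-averaged densities, or a
    non-converged result with diagnostics if neither is reached after one
    automatic doubling of the horizon.
    """
    options = options or SolverOptions()
    arr = config.arrays()
    init = init or default_initial_state(config)
    y = np.maximum(arr.pack(init.N, init.P, init.R), 0.0)
    thr = options.extinction_threshold

    def result_from(y, converged, oscillatory, t_end):
        N, P, R = arr.unpack(y)
        survivors = tuple(int(i) for i in np.flatnonzero(N >= thr))
        pred = tuple(int(h) for h in np.flatnonzero(P >= thr))
        return EquilibriumResult(
            state=CommunityState(N, P, R, t=t_end),
            survivors=survivors,
            predator_survivors=pred,
            converged=converged,
            oscillatory=oscillatory,
            residual=_residual(arr, y, thr),
            t_end=t_end,
            extinction_threshold=thr,
        )

    def active_sets(y):
        N, P, _ = arr.unpack(y)
        return np.flatnonzero(N > 0), np.flatnonzero(P > 0)

    def subthreshold_recovering(y) -> bool:
        """True if some rare population is growing (still assembling)."""
        N, P, R = arr.unpack(y)
        gN = arr.per_capita_growth(N, P, R)
        if np.any((N > 0) & (N < thr) & (gN > 0)):
            return True
        gP = arr.predator_per_capita(N)
        return bool(np.any((P > 0) & (P < thr) & (gP > 0)))

    t = 0.0
    # horizon ladder: one guaranteed doubling, further doublings only while a
    # slow near-equilibrium endgame (small residual) is still sorting itself out
    horizons = [options.t_max * 2**k for k in range(6)]
    for ih, horizon in enumerate(horizons):
        if ih >= 2 and _residual(arr, y, thr) >= 1e-3:
            break
        chunk = max(horizon / 200.0, 10.0)
        while t < horizon:
            t1 = min(t + chunk, horizon)
            an, ap = active_sets(y)
            sys = _LogSystem(arr, an, ap)
            sol = _integrate_log(sys, sys.to_log(y), t, t1, options, t_eval=np.array([t1]))
            y = sys.to_linear(sol.y[:, -1])
            t = t1
            res = _residual(arr, y, thr)
            if res < max(1e-4, options.equilibrium_tol) and not subthreshold_recovering(y):
                polished = _polish(arr, y, thr)
                if polished is not None and (
                    _residual(arr, polished, thr) < options.equilibrium_tol
                ):
                    return result_from(polished, converged=True, oscillatory=False, t_end=t)
                if res < options.equilibrium_tol:
                    return result_from(y, converged=True, oscillatory=False, t_end=t)
                if t > horizon / 4:
                    polished = _endgame_polish(arr, y, thr, options.equilibrium_tol)
                    if polished is not None:
                        return result_from(polished, converged=True, oscillatory=False, t_end=t)
            chunk = min(chunk * 1.6, horizon / 5.0)
        # horizon exhausted: resolve a slow exclusion endgame if one is underway
        if _residual(arr, y, thr) < 1e-2:
            polished = _endgame_polish(arr, y, thr, options.equilibrium_tol)
            if polished is not None:
                return result_from(polished, converged=True, oscillatory=False, t_end=t)
        # otherwise check the trailing window for oscillation
        osc = _oscillation_average(arr, y, t, options)
        if osc is not None:
            y_avg, decaying = osc
            polished = _polish(arr, y_avg, thr)
            good_root = polished is not None and (
                _residual(arr, polished, thr) < options.equilibrium_tol
            )
            if good_root and (decaying or _locally_stable(arr, polished, thr)):
                # damped spiral ringing around a stable equilibrium
                return result_from(polished, converged=True, oscillatory=False, t_end=t)
            if not decaying:
                # sustained cycle (around an unstable interior state)
                return result_from(y_avg, converged=False, oscillatory=True, t_end=t)
            y = y_avg  # decaying but not yet polishable: keep integrating
    return result_from(y, converged=False, oscillatory=False, t_end=t)


def _oscillation_average(arr, y, t_now, options):
    """Sample a trailing window; detect oscillation and whether it is decaying.

    Returns ``(window-mean state, decaying)`` when the window shows variation
    (CV > 1e-3 in some extant density) without secular trend (half-window
    means agree within 5%): ``decaying=True`` marks a damped spiral (the
    amplitude shrank by >20% between half-windows), ``decaying=False`` a
    sustained cycle to be reported as a cycle-averaged equilibrium.
    Returns None when the window is neither stationary nor oscillating.
    """
    thr = options.extinction_threshold
    t_win = options.window * options.t_max
    N0, P0, _ = arr.unpack(y)
    sys = _LogSystem(arr, np.flatnonzero(N0 > 0), np.flatnonzero(P0 > 0))
    te = np.linspace(t_now, t_now + t_win, 400)
    sol = _integrate_log(sys, sys.to_log(y), t_now, t_now + t_win, options, t_eval=te)
    Y = np.stack([sys.to_linear(col) for col in sol.y.T], axis=1)
    means = Y.mean(axis=1)
    extant = means > thr
    if not extant.any():
        return Y[:, -1], True
    cv = Y[extant].std(axis=1) / means[extant]
    half = Y.shape[1] // 2
    m1 = Y[extant, :half].mean(axis=1)
    m2 = Y[extant, half:].mean(axis=1)
    drift = np.abs(m2 - m1) / np.maximum(means[extant], 1e-300)
    # the no-trend requirement applies to robustly extant populations only;
    # near-threshold species may still be on a slow exclusion path inside the
    # cycle without invalidating the cycle average
    robust = means[extant] > 100 * thr
    max_drift = np.max(drift[robust]) if robust.any() else np.max(drift)
    if np.max(cv) > 1e-3 and max_drift < 0.05:
        y_avg = means.copy()
        y_avg[~extant] = 0.0
        cv1 = Y[extant, :half].std(axis=1) / np.maximum(m1, 1e-300)
        cv2 = Y[extant, half:].std(axis=1) / np.maximum(m2, 1e-300)
        decaying = bool(np.max(cv2) < 0.8 * np.max(cv1))
        return y_avg, decaying
    return None


# --------------------------------------------------------------------------
# trajectory simulation (linear space, threshold pinning per the contract)


def _integrate_chunk(arr, y, t0, t1, options, t_eval=None):
    sol = solve_ivp(
        arr.ode(), (t0, t1), y,
        method="LSODA", rtol=options.rtol, atol=options.atol, t_eval=t_eval,
    )
    if not sol.success:
        N, P, R = arr.unpack(np.maximum(sol.y[:, -1], 0.0))
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.3g}: {sol.message}",
            last_state=CommunityState(N, P, R, t=float(sol.t[-1])),
        )
    return sol


def simulate(
    config: FoodWebConfig,
    init: CommunityState | None = None,
    options: SolverOptions | None = None,
    n_points: int = 201,
) -> Trajectory:
    """Integrate the community over ``[0, t_max]`` and return the trajectory.

    Densities are clipped at zero; populations below the extinction threshold
    whose per-capita growth is negative are pinned to zero between sampling
    chunks and stay extinct thereafter.
    """
    options = options or SolverOptions()
    arr = config.arrays()
    init = init or default_initial_state(config)
    y = np.maximum(arr.pack(init.N, init.P, init.R), 0.0)
    thr = options.extinction_threshold
    t_grid = np.linspace(0.0, options.t_max, n_points)
    n_chunks = 20
    edges = np.linspace(0.0, options.t_max, n_chunks + 1)
    rows = {0.0: y.copy()}

    def pin(y):
        N, P, R = arr.unpack(y)
        gN = arr.per_capita_growth(N, P, R)
        N = np.where((N < thr) & (gN < 0), 0.0, N)
        gP = arr.predator_per_capita(N)
        P = np.where((P < thr) & (gP < 0), 0.0, P)
        return arr.pack(N, P, np.maximum(R, 0.0))

    for t0, t1 in zip(edges[:-1], edges[1:]):
        te = t_grid[(t_grid > t0) & (t_grid <= t1)]
        te = np.unique(np.append(te, t1))
        sol = _integrate_chunk(arr, y, t0, t1, options, t_eval=te)
        for tt, yy in zip(sol.t, sol.y.T):
            rows[float(tt)] = np.maximum(yy, 0.0)
        y = pin(np.maximum(sol.y[:, -1], 0.0))
        rows[float(t1)] = y.copy()
    ts = np.array(sorted(rows))
    Y = np.array([rows[t] for t in ts])
    n, l = arr.n, arr.l
    return Trajectory(t=ts, N=Y[:, :n], P=Y[:, n : n + l], R=Y[:, n + l :])


def richness(result: EquilibriumResult) -> int:
    """Number of surviving consumer species (predators counted separately)."""
    if not (result.converged or result.oscillatory):
        raise ValueError(
            "richness undefined: equilibrium search neither converged nor "
            "settled on a cycle"
        )
    return len(result.survivors)
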