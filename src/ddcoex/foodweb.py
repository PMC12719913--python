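"""Core food-web types and the generalized consumer-resource-predator dynamics.

The model is a chemostat-style community of ``n`` consumer species feeding on
``k`` substitutable resources with linear functional responses, optionally
preyed upon by ``l`` predators, with negative density dependence entering as a
per-capita mortality term ``mq * N**(x-1)`` (quadratic for the default
``x = 2``):

    dN_i/dt = N_i * ( sum_j mu_ij R_j - m_i - sum_h g_hi P_h - mq_i N_i^(x_i-1) )
    dP_h/dt = P_h * ( sum_i f_hi N_i - mp_h )
    dR_j/dt = a * (s_j - R_j) - sum_i V_ij N_i R_j

Every module studied by the package -- the two-species/two-resource web, the
three-species generalist web, the diamond web (one resource, one shared
predator) and the many-species bottom-up / top-down guilds -- is a special
case of this right-hand side obtained by zeroing blocks of the trait matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SpeciesTraits",
    "PredatorTraits",
    "ResourceEnvironment",
    "FoodWebConfig",
    "CommunityState",
    "Derivative",
    "rhs",
    "validate_config",
]


class ConfigError(ValueError):
    """Raised when a food-web configuration violates a structural invariant."""


def _vec(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ConfigError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SpeciesTraits:
    """Traits of one consumer species.

    Parameters
    ----------
    mu : array-like
        Per-resource intrinsic growth coefficients (rate per unit resource
        concentration), one entry per resource.
    V : array-like
        Per-resource consumption rates; yields are ``Y_j = mu_j / V_j``.
    g : array-like, optional
        Per-predator vulnerability (predation loss coefficient), one entry per
        predator; empty for predator-free webs.
    m : float
        Linear (density-independent) mortality rate.
    mq : float
        Density-dependent mortality coefficient; ``mq = 0`` recovers classic
        resource competition theory.
    x : float
        Mortality exponent (> 1); the per-capita loss is ``mq * N**(x-1)``,
        quadratic total mortality at the default ``x = 2``.
    """

    mu: np.ndarray
    V: np.ndarray
    g: np.ndarray = field(default_factory=lambda: np.zeros(0))
    m: float = 0.1
    mq: float = 0.0
    x: float = 2.0

    def __post_init__(self) -> None:
        self.mu = _vec(self.mu, "mu")
        self.V = _vec(self.V, "V")
        self.g = _vec(self.g, "g")
        self.m = float(self.m)
        self.mq = float(self.mq)
        self.x = float(self.x)

    @property
    def yields(self) -> np.ndarray:
        """Per-resource yields Y_j = mu_j / V_j (0 where both vanish)."""
        out = np.zeros_like(self.mu)
        np.divide(self.mu, self.V, out=out, where=self.V > 0)
        return out

    def violations(self, n_resources: int | None = None, n_predators: int | None = None) -> list[str]:
        v: list[str] = []
        if np.any(self.mu < 0):
            v.append("mu has negative entries")
        if np.any(self.V < 0):
            v.append("V has negative entries")
        if np.any(self.g < 0):
            v.append("g has negative entries")
        if self.m < 0:
            v.append(f"m is negative ({self.m})")
        if self.mq < 0:
            v.append(f"mq is negative ({self.mq})")
        if not self.x > 1:
            v.append(f"mortality exponent x must exceed 1 (got {self.x})")
        if len(self.mu) != len(self.V):
            v.append(f"mu ({len(self.mu)}) and V ({len(self.V)}) lengths differ")
        if n_resources is not None and len(self.mu) != n_resources:
            v.append(f"mu length {len(self.mu)} != resource count {n_resources}")
        if n_predators is not None and len(self.g) != n_predators:
            v.append(f"g length {len(self.g)} != predator count {n_predators}")
        return v


@dataclass
class PredatorTraits:
    """Traits of one predator: per-prey assimilation rates and mortality."""

    f: np.ndarray
    mp: float = 0.1

    def __post_init__(self) -> None:
        self.f = _vec(self.f, "f")
        self.mp = float(self.mp)

    @property
    def diet(self) -> tuple[int, ...]:
        """Indices of prey species with nonzero assimilation."""
        return tuple(int(i) for i in np.flatnonzero(self.f > 0))

    def violations(self, n_species: int | None = None) -> list[str]:
        v: list[str] = []
        if np.any(self.f < 0):
            v.append("f has negative entries")
        if not self.mp > 0:
            v.append(f"mp must be positive (got {self.mp})")
        if n_species is not None and len(self.f) != n_species:
            v.append(f"f length {len(self.f)} != species count {n_species}")
        return v


@dataclass
class ResourceEnvironment:
    """Resource supply: concentrations ``s`` and dilution rate ``a``.

    ``fixed=True`` holds resource concentrations constant at ``s`` (the
    top-down guild idealization in which resources never constrain the
    consumers); the resource derivative is then identically zero.
    """

    s: np.ndarray
    a: float = 1.0
    fixed: bool = False

    def __post_init__(self) -> None:
        self.s = _vec(self.s, "s")
        self.a = float(self.a)

    def violations(self) -> list[str]:
        v: list[str] = []
        if np.any(self.s < 0):
            v.append("supply s has negative entries")
        if not self.a > 0:
            v.append(f"dilution rate a must be positive (got {self.a})")
        return v


@dataclass
class FoodWebConfig:
    """Full parameterization of a community."""

    species: list[SpeciesTraits]
    predators: list[PredatorTraits] = field(default_factory=list)
    environment: ResourceEnvironment = field(
        default_factory=lambda: ResourceEnvironment(s=np.ones(1))
    )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_predators(self) -> int:
        return len(self.predators)

    @property
    def n_resources(self) -> int:
        return len(self.environment.s)

    # -- validation ------------------------------------------------------

    def violations(self) -> list[str]:
        v = [f"environment: {msg}" for msg in self.environment.violations()]
        k, l, n = self.n_resources, self.n_predators, self.n_species
        for i, sp in enumerate(self.species):
            v += [f"species[{i}]: {msg}" for msg in sp.violations(k, l)]
        for h, pr in enumerate(self.predators):
            v += [f"predators[{h}]: {msg}" for msg in pr.violations(n)]
        return v

    def require_valid(self) -> "FoodWebConfig":
        v = self.violations()
        if v:
            raise ConfigError("; ".join(v))
        return self

    # -- convenience -----------------------------------------------------

    def with_supply(self, s) -> "FoodWebConfig":
        """Copy of this config with a new supply vector (or scalar)."""
        env = replace(self.environment, s=_vec(s, "s"))
        return FoodWebConfig(self.species, self.predators, env)

    def arrays(self) -> "WebArrays":
        return WebArrays.from_config(self)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "mu": sp.mu.tolist(),
                    "V": sp.V.tolist(),
                    "g": sp.g.tolist(),
                    "m": sp.m,
                    "mq": sp.mq,
                    "x": sp.x,
                }
                for sp in self.species
            ],
            "predators": [
                {"f": pr.f.tolist(), "mp": pr.mp} for pr in self.predators
            ],
            "environment": {
                "s": self.environment.s.tolist(),
                "a": self.environment.a,
                "fixed": self.environment.fixed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoodWebConfig":
        species = [
            SpeciesTraits(
                mu=sp["mu"],
                V=sp["V"],
                g=sp.get("g", np.zeros(len(d.get("predators", [])))),
                m=sp.get("m", 0.1),
                mq=sp.get("mq", 0.0),
                x=sp.get("x", 2.0),
            )
            for sp in d["species"]
        ]
        predators = [
            PredatorTraits(f=pr["f"], mp=pr.get("mp", 0.1))
            for pr in d.get("predators", [])
        ]
        env = d["environment"]
        environment = ResourceEnvironment(
            s=env["s"], a=env.get("a", 1.0), fixed=env.get("fixed", False)
        )
        return cls(species, predators, environment)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "FoodWebConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class CommunityState:
    """Instantaneous densities of consumers (N), predators (P) and resources (R)."""

    N: np.ndarray
    P: np.ndarray
    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N = _vec(self.N, "N") if np.size(self.N) else np.zeros(0)
        self.P = _vec(self.P, "P") if np.size(self.P) else np.zeros(0)
        self.R = _vec(self.R, "R")
        self.t = float(self.t)


class Derivative(NamedTuple):
    """Time derivatives of a CommunityState."""

    dN: np.ndarray
    dP: np.ndarray
    dR: np.ndarray


class WebArrays:
    """Dense trait matrices compiled from a config, for fast evaluation.

    Attributes
    ----------
    MU, Vm : (n, k) growth and consumption matrices.
    Gm : (n, l) vulnerability of species i to predator h.
    F : (l, n) assimilation of predator h on species i.
    """

    __slots__ = ("MU", "Vm", "Gm", "m", "mq", "x", "F", "mp", "s", "a", "fixed",
                 "n", "l", "k")

    def __init__(self, MU, Vm, Gm, m, mq, x, F, mp, s, a, fixed):
        self.MU, self.Vm, self.Gm = MU, Vm, Gm
        self.m, self.mq, self.x = m, mq, x
        self.F, self.mp = F, mp
        self.s, self.a, self.fixed = s, a, fixed
        self.n, self.k = MU.shape
        self.l = F.shape[0]

    @classmethod
    def from_config(cls, config: FoodWebConfig) -> "WebArrays":
        config.require_valid()
        n, l, k = config.n_species, config.n_predators, config.n_resources
        MU = np.array([sp.mu for sp in config.species]).reshape(n, k)
        Vm = np.array([sp.V for sp in config.species]).reshape(n, k)
        Gm = (
            np.array([sp.g for sp in config.species]).reshape(n, l)
            if l
            else np.zeros((n, 0))
        )
        m = np.array([sp.m for sp in config.species])
        mq = np.array([sp.mq for sp in config.species])
        x = np.array([sp.x for sp in config.species])
        F = (
            np.array([pr.f for pr in config.predators]).reshape(l, n)
            if l
            else np.zeros((0, n))
        )
        mp = np.array([pr.mp for pr in config.predators])
        env = config.environment
        return cls(MU, Vm, Gm, m, mq, x, F, mp, env.s.copy(), env.a, env.fixed)

    # flat state layout: [N (n), P (l), R (k)]
    def pack(self, N, P, R) -> np.ndarray:
        return np.concatenate([np.atleast_1d(N), np.atleast_1d(P), np.atleast_1d(R)])

    def unpack(self, y: np.ndarray):
        n, l = self.n, self.l
        return y[:n], y[n : n + l], y[n + l :]

    def per_capita_growth(self, N, P, R) -> np.ndarray:
        """Per-capita consumer growth including the density-dependent loss."""
        Nc = np.maximum(N, 0.0)
        dd = self.mq * np.where(Nc > 0, Nc, 0.0) ** (self.x - 1.0)
        return self.MU @ R - self.m - self.Gm @ P - dd

    def invasion_rates(self, P, R) -> np.ndarray:
        """Per-capita consumer growth at vanishing density (no self-limitation)."""
        return self.MU @ R - self.m - self.Gm @ P

    def predator_per_capita(self, N) -> np.ndarray:
        return self.F @ N - self.mp

    def resource_rate(self, N, R) -> np.ndarray:
        if self.fixed:
            return np.zeros_like(R)
        return self.a * (self.s - R) - R * (self.Vm.T @ N)

    def deriv(self, y: np.ndarray) -> np.ndarray:
        N, P, R = self.unpack(y)
        dN = N * self.per_capita_growth(N, P, R)
        dP = P * self.predator_per_capita(N)
        dR = self.resource_rate(N, R)
        return np.concatenate([dN, dP, dR])

    def ode(self):
        """Right-hand side callable ``f(t, y)`` for scipy integrators."""
        return lambda t, y: self.deriv(y)


def rhs(config: FoodWebConfig, state: CommunityState) -> Derivative:
    """Evaluate the community time derivatives at ``state``.

    With no predators and two resources this is the two-species substitutable
    resource model; with one resource and one shared predator it is the
    diamond food web; the bottom-up and top-down guild equations are the
    same expressions restricted to their nonzero trait blocks.
    """
    arr = config.arrays()
    if len(state.N) != arr.n or len(state.P) != arr.l or len(state.R) != arr.k:
        raise ConfigError(
            f"state dimensions (n={len(state.N)}, l={len(state.P)}, k={len(state.R)}) "
            f"do not match config (n={arr.n}, l={arr.l}, k={arr.k})"
        )
    d = arr.deriv(arr.pack(state.N, state.P, state.R))
    dN, dP, dR = arr.unpack(d)
    return Derivative(dN=dN, dP=dP, dR=dR)


def validate_config(config: FoodWebConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    return config.violations()
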