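"""Surface-tension isotherm model, priors, noise model, and likelihood.

The surface tension of an aqueous surfactant solution decreases with bulk
surfactant concentration ``c`` until the critical micelle concentration (CMC,
``c*``) is reached, beyond which the air--water interface is saturated and the
surface tension plateaus.  Below the CMC the isotherm is described by the
Langmuir--Szyszkowski equation

    gamma(c) = gamma0 - a * ln(1 + k * c),        c < c*

and above it by the constant value attained at ``c*``.  All concentrations are
in mol/m^3 (numerically equal to mM) and surface tensions in N/m.

This module holds the domain types (parameters, measurements, priors, noise)
and the probabilistic primitives — model evaluation, log-prior, log-likelihood
and the unnormalized log-posterior — that the sampler and the design loop
consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "IsothermParams",
    "Measurement",
    "Dataset",
    "PriorSpec",
    "NoiseModel",
    "evaluate_isotherm",
    "log_prior_density",
    "log_likelihood",
    "log_unnormalized_posterior",
    "simulate_measurement",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class IsothermParams:
    """The 4-vector theta = (gamma0, a, k, cmc) of the surface-tension isotherm.

    Attributes
    ----------
    gamma0 : float
        Surface tension of the pure solvent [N/m].
    a : float
        Surface-pressure scale related to the molecular cross-section at the
        interface [N/m].
    k : float
        Langmuir equilibrium constant (affinity for the interface) [m^3/mol].
    cmc : float
        Critical micelle concentration c* [mol/m^3].
    """

    gamma0: float
    a: float
    k: float
    cmc: float

    def __post_init__(self) -> None:
        for name in ("gamma0", "a", "k", "cmc"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"IsothermParams.{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma0, self.a, self.k, self.cmc], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "IsothermParams":
        g0, a, k, cmc = (float(x) for x in arr)
        return cls(gamma0=g0, a=a, k=k, cmc=cmc)


PARAM_NAMES = ("gamma0", "a", "k", "cmc")


@dataclass(frozen=True)
class Measurement:
    """One surface-tension measurement (c, gamma_obs).

    ``label`` tags the campaign iteration in which the point was acquired;
    label 0 marks the two manual initialization measurements.  The in-memory
    type only requires finite values (simulated campaigns with extreme
    parameter draws may produce unphysical surface tensions); the physical
    sanity bound gamma_obs in (0, 0.2) N/m is enforced when reading lab CSV
    files (see :mod:`cmcbed.io`).
    """

    concentration: float
    surface_tension: float
    label: Optional[int] = None

    def __post_init__(self) -> None:
        c = self.concentration
        if not (np.isfinite(c) and c >= 0):
            raise ValueError(f"concentration must be finite and >= 0, got {c!r}")
        if not np.isfinite(self.surface_tension):
            raise ValueError(f"surface_tension must be finite, got {self.surface_tension!r}")


@dataclass
class Dataset:
    """Ordered collection of measurements; acquisition order is meaningful."""

    measurements: list[Measurement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self) -> Iterator[Measurement]:
        return iter(self.measurements)

    def append(self, m: Measurement) -> None:
        self.measurements.append(m)

    def extended(self, extra: Iterable[Measurement]) -> "Dataset":
        """A new Dataset with ``extra`` appended (original left untouched)."""
        return Dataset(list(self.measurements) + list(extra))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([m.concentration for m in self.measurements], dtype=float)

    @property
    def surface_tensions(self) -> np.ndarray:
        return np.array([m.surface_tension for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Prior over theta.

    gamma0 is Gaussian around the measured pure-water surface tension;
    k and a are uniform on generous intervals; the CMC prior is either
    uniform on [cmc_min, cmc_max] or log-uniform (uniform in ln c*).
    """

    gamma0_mean: float = 0.0718
    gamma0_sd: float = 0.001
    k_bounds: tuple[float, float] = (0.0, 10000.0)
    a_bounds: tuple[float, float] = (0.001, 0.1)
    cmc_bounds: tuple[float, float] = (0.0, 30.0)
    cmc_prior_kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.gamma0_sd <= 0:
            raise ValueError("gamma0_sd must be > 0")
        for name in ("k_bounds", "a_bounds", "cmc_bounds"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError(f"{name} must be a finite interval of positive width")
        if self.cmc_prior_kind not in ("uniform", "log_uniform"):
            raise ValueError(f"unknown cmc_prior_kind {self.cmc_prior_kind!r}")
        if self.cmc_prior_kind == "log_uniform" and self.cmc_bounds[0] <= 0:
            raise ValueError("log_uniform cmc prior requires a strictly positive lower bound")


@dataclass(frozen=True)
class NoiseModel:
    """Homoskedastic Gaussian measurement noise with known sd sigma [N/m]."""

    sigma: float = 0.001

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")


def evaluate_isotherm(theta: IsothermParams, c):
    """Surface tension gamma(c; theta) of the piecewise Langmuir-Szyszkowski model.

    gamma0 - a*ln(1 + k*c) for c < c*, constant at the c* value for c >= c*.
    Vectorized over ``c``; natural logarithm throughout.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(c_arr)) or np.any(c_arr < 0):
        raise ValueError("concentrations must be finite and non-negative")
    ceff = np.minimum(c_arr, theta.cmc)
    out = theta.gamma0 - theta.a * np.log1p(theta.k * ceff)
    return out if out.ndim else float(out)


def log_prior_density(theta: IsothermParams, prior: PriorSpec) -> float:
    """Log prior density of theta in nats; -inf outside any support.

    Gaussian for gamma0; uniform for k on (k_lo, k_hi] (open at 0 — k = 0
    yields a flat isotherm with a non-identifiable CMC); uniform for a; and
    uniform or log-uniform (density proportional to 1/c*, normalized) for c*.
    """
    lp = 0.0
    # gamma0 ~ N(mean, sd^2)
    z = (theta.gamma0 - prior.gamma0_mean) / prior.gamma0_sd
    lp += -0.5 * _LOG_2PI - math.log(prior.gamma0_sd) - 0.5 * z * z

    k_lo, k_hi = prior.k_bounds
    if not (max(k_lo, 0.0) < theta.k <= k_hi):
        return -np.inf
    lp += -math.log(k_hi - k_lo)

    a_lo, a_hi = prior.a_bounds
    if not (a_lo <= theta.a <= a_hi):
        return -np.inf
    lp += -math.log(a_hi - a_lo)

    c_lo, c_hi = prior.cmc_bounds
    if not (c_lo <= theta.cmc <= c_hi):
        return -np.inf
    if prior.cmc_prior_kind == "uniform":
        lp += -math.log(c_hi - c_lo)
    else:  # log_uniform: p(c*) = 1 / (c* * ln(c_hi/c_lo))
        lp += -math.log(theta.cmc) - math.log(math.log(c_hi / c_lo))
    return lp


def log_likelihood(theta: IsothermParams, data: Dataset, noise: NoiseModel) -> float:
    """Gaussian log likelihood of the dataset under theta; 0 for empty data."""
    n = len(data)
    if n == 0:
        return 0.0
    resid = evaluate_isotherm(theta, data.concentrations) - data.surface_tensions
    s = noise.sigma
    if s == 0:
        return 0.0 if np.all(resid == 0) else -np.inf
    out = -0.5 * n * (_LOG_2PI + 2.0 * math.log(s)) - 0.5 * float(np.sum((resid / s) ** 2))
    return out if np.isfinite(out) else -np.inf


def log_unnormalized_posterior(
    theta: IsothermParams, data: Dataset, prior: PriorSpec, noise: NoiseModel
) -> float:
    """log prior + log likelihood; the evidence p(D) is constant in theta and omitted."""
    lp = log_prior_density(theta, prior)
    if lp == -np.inf:
        return -np.inf
    return lp + log_likelihood(theta, data, noise)


def simulate_measurement(
    theta: IsothermParams,
    c: float,
    noise: NoiseModel,
    rng: np.random.Generator | int,
    label: Optional[int] = None,
) -> Measurement:
    """Draw one noisy measurement gamma_obs = gamma(c; theta) + N(0, sigma^2).

    ``rng`` may be a Generator or an integer seed; the same seed always
    reproduces the same draw.
    """
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mu = evaluate_isotherm(theta, float(c))
    g = float(mu + noise.sigma * gen.standard_normal())
    if not np.isfinite(g):
        raise RuntimeError("simulated surface tension is non-finite")
    return Measurement(concentration=float(c), surface_tension=g, label=label)
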