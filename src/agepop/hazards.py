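"""Lifetime distributions and their per-step hazard discretization.

A discrete-time survival (or development) process is specified by the
cumulative probability ``f(tau)`` that the event (death, or completion of
development) has occurred before the start of iteration ``tau``.  The
conditional probability of the event occurring *during* iteration ``tau`` is
the discrete hazard

    h(tau) = (f(tau + 1) - f(tau)) / (1 - f(tau))      if f(tau) != 1
    h(tau) = 1                                         otherwise

Four lifetime families are supported:

``FIXED_PROB``
    memoryless, geometric lifetime: constant per-step probability.
``FIXED_DURATION``
    deterministic lifetime of ``d`` steps: the hazard is 0 until it fires
    with certainty during iteration ``d - 1``.
``GAMMA``
    gamma-distributed lifetime with mean ``mu`` and standard deviation
    ``sigma`` (shape k = mu^2/sigma^2, scale theta = sigma^2/mu), discretised
    through the regularized lower incomplete gamma function.
``NBINOM``
    negative-binomial lifetime (p = mu/sigma^2, r = mu^2/(sigma^2 - mu)),
    defined only for sigma^2 > mu; r may be non-integer (Polya case).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import special as sc

__all__ = [
    "Family",
    "ParameterError",
    "LifetimeParams",
    "HazardCache",
    "lifetime_cdf",
    "hazard_step",
    "lifetime_pmf",
    "cached_hazard",
]

#: Below this survival mass the hazard is forced to 1 to avoid catastrophic
#: cancellation deep in the distribution tail.
TAIL_GUARD = 1e-12


class Family(enum.Enum):
    """Supported lifetime-distribution families."""

    FIXED_PROB = "fixed_prob"
    FIXED_DURATION = "fixed_duration"
    GAMMA = "gamma"
    NBINOM = "nbinom"


class ParameterError(ValueError):
    """Raised when lifetime parameters are outside the family's domain."""


@dataclass(frozen=True)
class LifetimeParams:
    """Validated parameters of one lifetime distribution.

    Exactly the fields relevant to ``family`` are set.  Use the constructor
    classmethods (:meth:`fixed_prob`, :meth:`fixed_duration`, :meth:`gamma`,
    :meth:`nbinom`) rather than the raw dataclass constructor.
    """

    family: Family
    prob: float | None = None
    duration: int | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family is Family.FIXED_PROB:
            if self.prob is None or not 0.0 <= self.prob <= 1.0:
                raise ParameterError(f"fixed probability must be in [0,1], got {self.prob}")
        elif self.family is Family.FIXED_DURATION:
            if self.duration is None or self.duration < 0 or self.duration != int(self.duration):
                raise ParameterError(f"duration must be a non-negative integer, got {self.duration}")
        elif self.family is Family.GAMMA:
            if self.mu is None or self.sigma is None or self.mu <= 0 or self.sigma <= 0:
                raise ParameterError(
                    f"gamma lifetime requires mu>0 and sigma>0, got mu={self.mu}, sigma={self.sigma}"
                )
        elif self.family is Family.NBINOM:
            if self.mu is None or self.sigma is None or self.mu <= 0:
                raise ParameterError(f"nbinom lifetime requires mu>0, got mu={self.mu}")
            if self.sigma is None or self.sigma**2 <= self.mu:
                raise ParameterError(
                    "negative-binomial lifetime requires sigma^2 > mu "
                    f"(got mu={self.mu}, sigma^2={None if self.sigma is None else self.sigma**2}); "
                    "the family is restrictive over the minimum allowed standard deviation"
                )

    # -- constructors -------------------------------------------------------

    @classmethod
    def fixed_prob(cls, prob: float) -> "LifetimeParams":
        return cls(Family.FIXED_PROB, prob=float(prob))

    @classmethod
    def fixed_duration(cls, duration: int) -> "LifetimeParams":
        return cls(Family.FIXED_DURATION, duration=int(duration))

    @classmethod
    def gamma(cls, mu: float, sigma: float) -> "LifetimeParams":
        # sigma == 0 degrades to a deterministic lifetime of round(mu) steps.
        if sigma == 0:
            return cls.fixed_duration(round(mu))
        return cls(Family.GAMMA, mu=float(mu), sigma=float(sigma))

    @classmethod
    def nbinom(cls, mu: float, sigma: float) -> "LifetimeParams":
        return cls(Family.NBINOM, mu=float(mu), sigma=float(sigma))

    # -- derived quantities (pure functions of mu, sigma) -------------------

    @property
    def gamma_shape(self) -> float:
        """k = mu^2 / sigma^2."""
        return self.mu**2 / self.sigma**2

    @property
    def gamma_scale(self) -> float:
        """theta = sigma^2 / mu."""
        return self.sigma**2 / self.mu

    @property
    def nbinom_p(self) -> float:
        """Success probability p = mu / sigma^2."""
        return self.mu / self.sigma**2

    @property
    def nbinom_r(self) -> float:
        """Number of successes r = mu^2 / (sigma^2 - mu); non-integer allowed."""
        return self.mu**2 / (self.sigma**2 - self.mu)


def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    return tau


def lifetime_cdf(params: LifetimeParams, tau):
    """Cumulative probability of the event before the start of iteration ``tau``.

    Accepts a scalar or an array of non-negative step counts; returns a float
    or an ndarray accordingly.  Monotone non-decreasing in ``tau`` and bounded
    in [0, 1] for every family.
    """
    tau = _check_tau(tau)
    if params.family is Family.FIXED_PROB:
        out = 1.0 - (1.0 - params.prob) ** np.asarray(tau, dtype=float)
    elif params.family is Family.FIXED_DURATION:
        out = (tau >= params.duration).astype(float)
    elif params.family is Family.GAMMA:
        out = sc.gammainc(params.gamma_shape, tau / params.gamma_scale)
    else:  # NBINOM: regularized incomplete beta I_p(r, tau + 1)
        out = sc.betainc(params.nbinom_r, tau + 1.0, params.nbinom_p)
    return float(out) if np.isscalar(tau) or tau.ndim == 0 else np.asarray(out, dtype=float)


def hazard_step(params: LifetimeParams, tau):
    """Per-step hazard: conditional event probability during iteration ``tau``.

    Returns ``(f(tau+1) - f(tau)) / (1 - f(tau))`` with the convention that the
    hazard is 1 whenever the remaining survival mass ``1 - f(tau)`` is below
    the tail guard.  Scalar or vectorised over ``tau``.
    """
    tau = _check_tau(tau)
    if params.family is Family.FIXED_PROB:
        # Memoryless: return the probability exactly, not via the CDF.
        out = np.broadcast_to(np.float64(params.prob), tau.shape).copy() if tau.ndim else params.prob
        return out
    if params.family is Family.FIXED_DURATION:
        out = (tau + 1 >= params.duration).astype(float)
        return float(out) if tau.ndim == 0 else out
    f0 = np.asarray(lifetime_cdf(params, tau), dtype=float)
    f1 = np.asarray(lifetime_cdf(params, tau + 1), dtype=float)
    surv = 1.0 - f0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(surv < TAIL_GUARD, 1.0, (f1 - f0) / np.where(surv < TAIL_GUARD, 1.0, surv))
    h = np.clip(h, 0.0, 1.0)
    return float(h) if tau.ndim == 0 else h


def lifetime_pmf(params: LifetimeParams, tau):
    """Probability that the event occurs during iteration ``tau``.

    Defined as the survival product times the step hazard,
    ``prod_{s<tau}(1 - h(s)) * h(tau)``, which telescopes to
    ``(f(tau+1) - f(tau)) / (1 - f(0))``.  Sums to 1 over tau for every valid
    parameter set (the negative-binomial CDF has mass at 0, hence the
    normalisation by ``1 - f(0)``).
    """
    tau = _check_tau(tau)
    f0 = np.asarray(lifetime_cdf(params, tau), dtype=float)
    f1 = np.asarray(lifetime_cdf(params, tau + 1), dtype=float)
    base = 1.0 - lifetime_cdf(params, 0)
    out = (f1 - f0) / base if base > 0 else np.where(np.asarray(tau) == 0, 1.0, 0.0)
    return float(out) if tau.ndim == 0 else np.asarray(out, dtype=float)


@dataclass
class HazardCache:
    """Memoization table for step hazards.

    Keys are the full-precision parameter tuple plus the step counter; no
    fuzzy matching.  The cache is transparent: a cached value is bit-identical
    to the directly computed value.  On reaching ``max_entries`` the whole
    table is dropped (the table can grow memory-intensive for long-lived
    strata, so it is bounded rather than unbounded).
    """

    max_entries: int = 1_048_576
    hits: int = 0
    misses: int = 0
    _table: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self._table)

    def clear(self) -> None:
        self._table.clear()


def cached_hazard(cache: HazardCache, params: LifetimeParams, tau: int) -> float:
    """Scalar :func:`hazard_step` with memoization through ``cache``."""
    key = (params.family, params.prob, params.duration, params.mu, params.sigma, int(tau))
    table = cache._table
    try:
        value = table[key]
        cache.hits += 1
        return value
    except KeyError:
        pass
    cache.misses += 1
    value = hazard_step(params, int(tau))
    if len(table) >= cache.max_entries:
        table.clear()
    table[key] = value
    return value
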