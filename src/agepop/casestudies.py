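"""Validation models built on the engine.

Four classic stage-structured systems, each exercising a different corner of
the engine:

* :func:`worked_example` -- a periodic development process (gonotrophic-cycle
  style): gamma development of 50 +/- 10 hours, repeated via reintroduction,
  with senescent survival whose mean lifetime shrinks with each completed
  cycle.
* :func:`blowflies` -- Nicholson's blowflies: five life stages with strict
  development durations and density-dependent fecundity; exhibits the famous
  quasi-cyclic adult oscillations.
* :func:`nicholson_bailey` -- host-parasitoid dynamics in discrete
  generations, optionally age-structured in the host (the Hastings variant,
  where only juveniles are parasitised and adults survive per a configurable
  lifetime regime).
* :func:`sir` -- an SIR epidemic whose infectious-period distribution is
  tracked individual-by-individual, from memoryless (sigma = mu) to fixed
  length (sigma = 0).

Default parameter values are data, shipped in ``data/case_params.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .hazards import ParameterError
from .population import AgeDevGroup, Population, ProcessSpec
from .simulate import Scenario, cycle_survival

__all__ = [
    "load_case_params",
    "worked_example",
    "BlowflyParams",
    "blowflies",
    "NBHParams",
    "nicholson_bailey",
    "SIRParams",
    "sir",
    "count_peaks",
]


def load_case_params() -> dict:
    """Load the shipped case-study parameter fixture."""
    ref = importlib.resources.files("agepop").joinpath("data/case_params.yaml")
    return yaml.safe_load(ref.read_text())


# ---------------------------------------------------------------------------
# Worked example: periodic gamma development with senescent survival
# ---------------------------------------------------------------------------

def worked_example(stochastic: bool = False, seed: int | None = None) -> Scenario:
    """Scenario: 1000 individuals, hourly steps, 20-day horizon.

    Development is gamma with mean 50 h and SD 10 h and is periodic (each
    completing stratum re-enters for the next cycle); survival is gamma with
    mean ``max(240, 480 - 48 * devcycle)`` hours and SD one tenth of the
    mean, so individuals senesce as they complete cycles.
    """
    return Scenario(
        cohorts=[AgeDevGroup(number=1000)],
        dev=ProcessSpec(mean=50.0 / 24.0, sd=10.0 / 24.0),
        death=cycle_survival(alpha=24.0),
        steps=480,
        alpha=24.0,
        stochastic=stochastic,
        seed=seed,
        reintroduce_developed=True,
    )


# ---------------------------------------------------------------------------
# Nicholson's blowflies
# ---------------------------------------------------------------------------

def _per_step_death_from_survival(daily_survival: float, alpha: float) -> float:
    return 1.0 - daily_survival ** (1.0 / alpha)


@dataclass
class BlowflyParams:
    """Five-stage blowfly life cycle (egg, larva, pupa, immature, adult).

    Durations are in days; juvenile survival is a per-day probability; adult
    mortality is a per-day rate; fecundity is eggs per adult per day with an
    exponential density-dependence scale in adults.
    """

    egg_duration_days: float = 0.6
    larva_duration_days: float = 5.0
    pupa_duration_days: float = 5.9
    immature_duration_days: float = 4.1
    egg_daily_survival: float = 1.0
    larva_daily_survival: float = 1.0
    pupa_daily_survival: float = 1.0
    immature_daily_survival: float = 1.0
    adult_daily_mortality: float = 0.27
    fecundity_per_adult_day: float = 8.5
    fecundity_scale_adults: float = 600.0
    initial_adults: float = 500.0
    alpha: float = 10.0
    horizon_days: float = 400.0

    def __post_init__(self) -> None:
        for name in ("egg", "larva", "pupa", "immature"):
            s = getattr(self, f"{name}_daily_survival")
            if not 0.0 <= s <= 1.0:
                raise ParameterError(f"{name} daily survival must be in [0,1]")
            if getattr(self, f"{name}_duration_days") <= 0:
                raise ParameterError(f"{name} duration must be positive")
        for dur in (self.egg_duration_days, self.larva_duration_days,
                    self.pupa_duration_days, self.immature_duration_days):
            steps = dur * self.alpha
            if abs(steps - round(steps)) > 1e-9:
                raise ParameterError(
                    f"stage duration {dur} d is not an integer number of steps at alpha={self.alpha}"
                )

    @classmethod
    def from_fixture(cls, **overrides) -> "BlowflyParams":
        values = load_case_params()["blowflies"] | overrides
        return cls(**values)


def blowflies(params: BlowflyParams | None = None, stochastic: bool = False,
              seed: int | None = None) -> pd.DataFrame:
    """Simulate the five-stage blowfly loop; one row per step.

    Juvenile stages develop for a strict duration under a fixed per-step
    survival probability; adults only die (fixed probability).  Each step the
    adults lay ``fecundity * exp(-A / scale) * A / alpha`` eggs (a Poisson
    draw in stochastic mode).
    """
    p = params or BlowflyParams.from_fixture()
    a = p.alpha
    rng = np.random.default_rng(seed)
    stages = ["egg", "larva", "pupa", "immature"]
    durations = {
        "egg": round(p.egg_duration_days * a),
        "larva": round(p.larva_duration_days * a),
        "pupa": round(p.pupa_duration_days * a),
        "immature": round(p.immature_duration_days * a),
    }
    death_prob = {
        s: _per_step_death_from_survival(getattr(p, f"{s}_daily_survival"), a)
        for s in stages
    }
    adult_death = 1.0 - np.exp(-p.adult_daily_mortality / a)

    pops = {s: Population(stochastic=stochastic, seed=rng.integers(2**31)) for s in stages}
    adults = Population(stochastic=stochastic, seed=rng.integers(2**31))
    n0 = int(p.initial_adults) if stochastic else p.initial_adults
    adults.add(number=n0)

    n_steps = int(round(p.horizon_days * a))
    rows = []
    for step in range(n_steps):
        A = adults.size
        rate = p.fecundity_per_adult_day * np.exp(-A / p.fecundity_scale_adults) * A / a
        eggs_in = int(rng.poisson(rate)) if stochastic else rate

        tables = {}
        for s in stages:
            res = pops[s].iterate(
                dev=ProcessSpec(mean=durations[s], sd=0.0),
                death=ProcessSpec(prob=death_prob[s]),
            )
            tables[s] = res.devtable
        adults.iterate(death=ProcessSpec(prob=adult_death))

        pops["larva"].reintroduce(tables["egg"])
        pops["pupa"].reintroduce(tables["larva"])
        pops["immature"].reintroduce(tables["pupa"])
        adults.reintroduce(tables["immature"])
        if eggs_in:
            pops["egg"].add(number=eggs_in)

        rows.append((step, step / a, pops["egg"].size, pops["larva"].size,
                     pops["pupa"].size, pops["immature"].size, adults.size))
    return pd.DataFrame(
        rows, columns=["step", "day", "eggs", "larvae", "pupae", "immatures", "adults"]
    )


def count_peaks(values, times=None, lo=None, hi=None, threshold_frac: float = 0.1) -> int:
    """Count local maxima of a series, unsmoothed.

    A peak is an index whose value strictly exceeds the previous differing
    value and is not exceeded by the next differing value (plateaus take
    their first index), and whose height exceeds ``threshold_frac`` times the
    global maximum of the full series.  If ``times`` with ``lo``/``hi`` are
    given, only peaks with ``lo <= time <= hi`` are counted.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        return 0
    # Compress plateaus to their first index, then take strict local maxima.
    starts = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
    w = v[starts]
    thresh = threshold_frac * v.max()
    peaks = [
        starts[j]
        for j in range(1, len(w) - 1)
        if w[j] > w[j - 1] and w[j] > w[j + 1] and w[j] > thresh
    ]
    if times is None:
        return len(peaks)
    times = np.asarray(times, dtype=float)
    return sum(
        1
        for i in peaks
        if (lo is None or times[i] >= lo) and (hi is None or times[i] <= hi)
    )


# ---------------------------------------------------------------------------
# Nicholson-Bailey host-parasitoid dynamics and the Hastings variant
# ---------------------------------------------------------------------------

@dataclass
class NBHParams:
    """Host-parasitoid parameters in discrete generations.

    ``survival`` selects the adult-host lifetime regime: ``("none",)`` for a
    semelparous host (no adult carry-over; with ``juvenile_stage_length`` 1
    this is exactly the classical two-parameter map),
    ``("fixed_prob", s)`` for age-independent survival probability ``s`` per
    generation, ``("fixed_duration", d)`` for a strict ``d``-generation adult
    lifespan, and ``("gamma", mu, sigma)`` for a gamma-distributed adult
    lifetime.
    """

    reproduction: float = 2.0
    searching_efficiency: float = 0.02
    juvenile_stage_length: int = 1
    survival: tuple = ("none",)
    initial_hosts: float = 60.0
    initial_parasites: float = 30.0
    generations: int = 120

    def __post_init__(self) -> None:
        if self.searching_efficiency <= 0:
            raise ParameterError("searching efficiency must be positive")
        kind = self.survival[0]
        if kind not in ("none", "fixed_prob", "fixed_duration", "gamma"):
            raise ParameterError(f"unknown survival regime {kind!r}")
        if kind == "gamma":
            _, mu, sigma = self.survival
            if mu <= 0 or sigma < 0:
                raise ParameterError("gamma survival requires mu>0 and sigma>=0")

    @classmethod
    def from_fixture(cls, **overrides) -> "NBHParams":
        raw = load_case_params()["nicholson_bailey"]
        values = dict(
            reproduction=raw["reproduction"],
            searching_efficiency=raw["searching_efficiency"],
            juvenile_stage_length=raw["juvenile_stage_length"],
            survival=("fixed_prob", raw["adult_survival_prob"]),
            initial_hosts=raw["initial_hosts"],
            initial_parasites=raw["initial_parasites"],
            generations=raw["generations"],
        )
        values.update(overrides)
        return cls(**values)


def _adult_death_spec(survival: tuple) -> ProcessSpec | None:
    kind = survival[0]
    if kind == "none":
        return None
    if kind == "fixed_prob":
        return ProcessSpec(prob=1.0 - survival[1])
    if kind == "fixed_duration":
        return ProcessSpec(mean=float(survival[1]), sd=0.0)
    return ProcessSpec(mean=float(survival[1]), sd=float(survival[2]))


def nicholson_bailey(params: NBHParams | None = None, age_structured: bool = True,
                     stochastic: bool = False, seed: int | None = None) -> pd.DataFrame:
    """Host-parasitoid generations; one row per generation.

    Parasitoids attack only the juvenile host class; a juvenile escapes with
    probability ``exp(-a P)``.  Parasitised juveniles become next
    generation's parasitoids.  Escaping juveniles mature after
    ``juvenile_stage_length`` generations into adults, which survive per the
    chosen lifetime regime and each produce ``reproduction`` new juveniles
    per generation.  Without age structure the whole host population is
    juvenile and semelparous, which collapses to the classical map
    ``H' = R H exp(-a P)``, ``P' = H (1 - exp(-a P))``.
    """
    p = params or NBHParams.from_fixture()
    if not age_structured:
        p = NBHParams(
            reproduction=p.reproduction,
            searching_efficiency=p.searching_efficiency,
            juvenile_stage_length=1,
            survival=("none",),
            initial_hosts=p.initial_hosts,
            initial_parasites=p.initial_parasites,
            generations=p.generations,
        )
    rng = np.random.default_rng(seed)
    juv = Population(stochastic=stochastic, seed=rng.integers(2**31))
    adults = Population(stochastic=stochastic, seed=rng.integers(2**31))
    h0 = int(p.initial_hosts) if stochastic else float(p.initial_hosts)
    juv.add(number=h0)
    parasites = int(p.initial_parasites) if stochastic else float(p.initial_parasites)
    death_spec = _adult_death_spec(p.survival)
    semelparous = p.survival[0] == "none"

    rows = []
    for gen in range(p.generations):
        hosts = juv.size + adults.size
        rows.append((gen, hosts, parasites, juv.size, adults.size))
        par_prob = -np.expm1(-p.searching_efficiency * parasites)
        res = juv.iterate(
            dev=ProcessSpec(mean=float(p.juvenile_stage_length), sd=0.0),
            death=ProcessSpec(prob=par_prob),
        )
        parasitised = res.dead
        if death_spec is not None:
            adults.iterate(death=death_spec)
        adults.reintroduce(res.devtable)
        A = adults.size
        eggs = p.reproduction * A
        if stochastic:
            eggs = int(rng.poisson(eggs))
        if eggs:
            juv.add(number=eggs)
        if semelparous:
            adults.empty()
        parasites = parasitised
    return pd.DataFrame(rows, columns=["generation", "hosts", "parasites",
                                       "juveniles", "adults"])


# ---------------------------------------------------------------------------
# SIR epidemic with an age-structured infectious period
# ---------------------------------------------------------------------------

@dataclass
class SIRParams:
    """SIR epidemic with explicit infectious-period distribution.

    ``transmission_per_day`` is the per-infectious, per-susceptible daily
    infection rate (force of infection ``beta * I``); the infectious period
    is gamma with mean ``infectious_mean_days`` and SD ``infectious_sd_days``
    (``sd = 0`` gives a precise length, ``sd = mean`` the memoryless
    limit of canonical compartment models).
    """

    transmission_per_day: float = 5.85e-4
    infectious_mean_days: float = 11.71
    infectious_sd_days: float = 5.85
    initial_susceptible: float = 254
    initial_infectious: float = 7
    horizon_days: float = 180.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.infectious_mean_days <= 0 or self.infectious_sd_days < 0:
            raise ParameterError("infectious period requires mean>0 and sd>=0")
        if self.transmission_per_day < 0:
            raise ParameterError("transmission rate must be non-negative")

    @classmethod
    def from_fixture(cls, **overrides) -> "SIRParams":
        raw = load_case_params()["eyam_sir"]
        values = dict(
            transmission_per_day=raw["transmission_per_day"],
            infectious_mean_days=raw["infectious_mean_days"],
            infectious_sd_days=raw["infectious_sd_days"],
            initial_susceptible=raw["initial_susceptible"],
            initial_infectious=raw["initial_infectious"],
            horizon_days=raw["horizon_days"],
            alpha=raw["alpha"],
        )
        values.update(overrides)
        return cls(**values)


def sir(params: SIRParams | None = None, stochastic: bool = False,
        seed: int | None = None) -> pd.DataFrame:
    """Run the epidemic; one row per step with columns day, S, I, R.

    The infectious pool is an engine population whose "development" is exit
    to the removed class, so each infectious individual's time in the stage
    is tracked and the exit hazard follows the configured gamma (or fixed)
    period.  New infections enter the pool with a fresh stage counter and
    experience the exit hazard from the next step on.
    """
    p = params or SIRParams.from_fixture()
    a = p.alpha
    rng = np.random.default_rng(seed)
    infectious = Population(stochastic=stochastic, seed=rng.integers(2**31))
    i0 = int(p.initial_infectious) if stochastic else float(p.initial_infectious)
    infectious.add(number=i0)
    S = int(p.initial_susceptible) if stochastic else float(p.initial_susceptible)
    R = 0 if stochastic else 0.0
    exit_spec = ProcessSpec(mean=p.infectious_mean_days * a, sd=p.infectious_sd_days * a)

    n_steps = int(round(p.horizon_days * a))
    rows = []
    for step in range(n_steps):
        I = infectious.size
        p_inf = -np.expm1(-p.transmission_per_day * I / a)
        new_inf = rng.binomial(S, p_inf) if stochastic else S * p_inf
        res = infectious.iterate(dev=exit_spec)
        R += res.developed
        if new_inf:
            infectious.add(number=new_inf)
            S -= new_inf
        rows.append((step, (step + 1) / a, S, infectious.size, R))
    return pd.DataFrame(rows, columns=["step", "day", "S", "I", "R"])
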