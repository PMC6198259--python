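"""Dynamically stratified age/stage population engine.

A population is an ordered collection of *strata* (age-development groups):
sets of individuals sharing identical counters

* ``age``          -- iterations alive since entering the population,
* ``devcycle``     -- completed development cycles,
* ``development``  -- iterations spent in the current cycle.

Each iteration applies a survival and a development process to every stratum.
Death is evaluated at the stratum's age counter, development at its
development counter.  In stochastic mode the numbers of dying and completing
individuals are binomial draws; in deterministic mode their expectations are
propagated, so the deterministic trajectory is exactly the mean of the
stochastic process.

Individuals completing development are removed from the population and
recorded in the ``devtable`` (with the development counter reset and the
cycle counter incremented); for periodic processes, such as gonotrophic
cycles, the devtable is typically fed straight back with
:meth:`Population.reintroduce`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .hazards import Family, LifetimeParams, ParameterError, hazard_step

__all__ = [
    "Mode",
    "AgeDevGroup",
    "StratumTable",
    "ProcessSpec",
    "IterationResult",
    "Population",
    "NOP",
]

_KEY_COLS = ("age", "devcycle", "development")

# Counters are packed into one int64 so key merging and lexicographic
# sorting reduce to 1-D integer operations; 21 bits per counter bounds each
# at 2**21 - 1 iterations, far beyond any practical horizon.
_KEY_BITS = 21
_KEY_MAX = (1 << _KEY_BITS) - 1


def _pack(keys: np.ndarray) -> np.ndarray:
    if len(keys) and keys.max() > _KEY_MAX:
        raise OverflowError(f"counter exceeds {_KEY_MAX}")
    return (keys[:, 0] << (2 * _KEY_BITS)) | (keys[:, 1] << _KEY_BITS) | keys[:, 2]


def _unpack(packed: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [packed >> (2 * _KEY_BITS), (packed >> _KEY_BITS) & _KEY_MAX, packed & _KEY_MAX]
    )


class Mode(enum.Enum):
    DETERMINISTIC = "deterministic"
    STOCHASTIC = "stochastic"


@dataclass(frozen=True)
class AgeDevGroup:
    """One stratum: counters plus the number of identical individuals."""

    age: int = 0
    devcycle: int = 0
    development: int = 0
    number: float = 0.0

    def __post_init__(self) -> None:
        if self.age < 0 or self.devcycle < 0 or self.development < 0:
            raise ValueError("counters must be non-negative")
        if self.number < 0:
            raise ValueError("number must be non-negative")


class StratumTable:
    """Immutable table of strata (keys sorted lexicographically)."""

    def __init__(self, keys: np.ndarray, numbers: np.ndarray):
        self.keys = np.asarray(keys, dtype=np.int64).reshape(-1, 3)
        self.numbers = np.asarray(numbers)

    def __len__(self) -> int:
        return len(self.numbers)

    @property
    def total(self):
        return self.numbers.sum() if len(self.numbers) else 0

    def groups(self) -> list[AgeDevGroup]:
        return [
            AgeDevGroup(int(a), int(c), int(d), n)
            for (a, c, d), n in zip(self.keys, self.numbers)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.keys[:, 0],
                "devcycle": self.keys[:, 1],
                "development": self.keys[:, 2],
                "number": self.numbers,
            }
        )

    @classmethod
    def empty(cls, stochastic: bool) -> "StratumTable":
        dtype = np.int64 if stochastic else np.float64
        return cls(np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=dtype))


@dataclass(frozen=True)
class ProcessSpec:
    """Description of one process (survival or development) for an iteration.

    Exactly one of the following is active, with fixed probability taking
    priority over the distribution parameters:

    * ``prob``        -- age-independent per-step probability;
    * ``mean, sd``    -- lifetime distribution in the population's default
                         family (``sd == 0`` selects a fixed duration of
                         ``round(mean)`` steps);
    * ``func``        -- callable mapping an :class:`AgeDevGroup` to a tuple
                         ``(prob, mean, sd)`` (unused entries ``None``),
                         evaluated once per stratum per step.  A callable with
                         attribute ``vectorized = True`` instead receives the
                         ``(n, 3)`` key array and returns three length-``n``
                         arrays (``NaN`` marking unused entries).
    """

    prob: float | None = None
    mean: float | None = None
    sd: float | None = None
    func: Callable | None = None

    def __post_init__(self) -> None:
        if self.prob is None and self.mean is None and self.func is None:
            raise ParameterError("empty process spec: set prob, (mean, sd), or func")

    def params(self, family: Family) -> LifetimeParams:
        """Resolve to concrete lifetime parameters (priority: prob first)."""
        if self.prob is not None:
            return LifetimeParams.fixed_prob(self.prob)
        if self.mean is None:
            raise ParameterError("process spec with func must be resolved per stratum")
        sd = 0.0 if self.sd is None else self.sd
        if sd == 0:
            return LifetimeParams.fixed_duration(round(self.mean))
        if family is Family.NBINOM:
            return LifetimeParams.nbinom(self.mean, sd)
        return LifetimeParams.gamma(self.mean, sd)


#: A process that never fires: survival and development left untouched.
NOP = ProcessSpec(prob=0.0)


@dataclass
class IterationResult:
    """Conservation-checked outcome of one iteration."""

    size: float
    dead: float
    developed: float
    devtable: StratumTable


class Population:
    """The engine: strata, one-step updates, and conservation bookkeeping.

    Parameters
    ----------
    stochastic:
        ``True`` for binomial sampling with integer counts, ``False`` for
        expectation dynamics with real counts.
    family:
        default lifetime family used when a process gives (mean, sd):
        ``"gamma"`` (continuous-time analogue) or ``"nbinom"`` (discrete).
    seed:
        seed of the population's private random generator (stochastic mode);
        with binomial draws taken in key-sorted stratum order, a seed fully
        determines a trajectory.
    """

    def __init__(self, stochastic: bool = False, family: str | Family = Family.GAMMA,
                 seed: int | None = None, prune_below: float = 0.0):
        family = Family(family) if not isinstance(family, Family) else family
        if family not in (Family.GAMMA, Family.NBINOM):
            raise ParameterError("default family must be gamma or nbinom")
        self.stochastic = bool(stochastic)
        #: deterministic strata at or below this size are dropped after each
        #: update; the default 0.0 prunes only exact zeros, so no mass is
        #: ever silently lost unless the caller opts in
        self.prune_below = float(prune_below)
        self.family = family
        self.rng = np.random.default_rng(seed)
        self.mode = Mode.STOCHASTIC if stochastic else Mode.DETERMINISTIC
        self._dtype = np.int64 if self.stochastic else np.float64
        self._keys = np.empty((0, 3), dtype=np.int64)
        self._num = np.empty(0, dtype=self._dtype)
        self.dead = 0
        self.developed = 0
        self.devtable = StratumTable.empty(self.stochastic)
        self._pruned_mass = 0.0

    # -- bookkeeping --------------------------------------------------------

    @property
    def size(self):
        """Total number of individuals (conserved by every iteration)."""
        total = self._num.sum() if len(self._num) else 0
        return int(total) if self.stochastic else float(total)

    def __len__(self) -> int:
        return len(self._num)

    def empty(self) -> None:
        """Remove all strata (the population object can be recycled)."""
        self._keys = np.empty((0, 3), dtype=np.int64)
        self._num = np.empty(0, dtype=self._dtype)
        self.devtable = StratumTable.empty(self.stochastic)
        self.dead = 0
        self.developed = 0

    def _store(self, keys: np.ndarray, nums: np.ndarray) -> None:
        keep = nums > (0 if self.stochastic else self.prune_below)
        self._pruned_mass = 0.0 if self.stochastic else float(nums[~keep].sum())
        keys, nums = keys[keep], nums[keep]
        order = np.argsort(_pack(keys), kind="stable")
        self._keys = np.ascontiguousarray(keys[order])
        self._num = np.ascontiguousarray(nums[order].astype(self._dtype))

    @staticmethod
    def _merge(keys: np.ndarray, nums: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sum numbers over duplicate keys; return sorted unique keys."""
        if len(keys) == 0:
            return keys, nums
        packed = _pack(keys)
        uniq, inverse = np.unique(packed, return_inverse=True)
        summed = np.zeros(len(uniq), dtype=nums.dtype)
        np.add.at(summed, inverse, nums)
        return _unpack(uniq), summed

    # -- construction -------------------------------------------------------

    def add(self, group: AgeDevGroup | None = None, *, age: int = 0, devcycle: int = 0,
            development: int = 0, number=0) -> None:
        """Insert individuals, merging with an existing stratum of equal key."""
        if group is None:
            group = AgeDevGroup(age, devcycle, development, number)
        if self.stochastic and group.number != int(group.number):
            raise ValueError("stochastic populations hold integer numbers of individuals")
        if group.number == 0:
            return
        key = np.array([[group.age, group.devcycle, group.development]], dtype=np.int64)
        num = np.array([group.number], dtype=self._dtype)
        keys, nums = self._merge(np.vstack([self._keys, key]),
                                 np.concatenate([self._num, num]))
        self._store(keys, nums)

    def reintroduce(self, devtable: StratumTable) -> None:
        """Feed a devtable back into the population (periodic development)."""
        if len(devtable) == 0:
            return
        if self.stochastic != np.issubdtype(devtable.numbers.dtype, np.integer):
            raise ValueError("devtable count type does not match population mode")
        keys, nums = self._merge(
            np.vstack([self._keys, devtable.keys]),
            np.concatenate([self._num, devtable.numbers.astype(self._dtype)]),
        )
        self._store(keys, nums)

    # -- hazard resolution --------------------------------------------------

    def _hazards(self, spec: ProcessSpec, taus: np.ndarray) -> np.ndarray:
        """Per-stratum event probabilities for one process at counters ``taus``."""
        n = len(taus)
        if spec.func is None:
            params = spec.params(self.family)
            return np.asarray(hazard_step(params, taus), dtype=float).reshape(n)
        if getattr(spec.func, "vectorized", False):
            prob, mean, sd = spec.func(self._keys)
            prob = np.full(n, np.nan) if prob is None else np.asarray(prob, dtype=float)
            mean = np.full(n, np.nan) if mean is None else np.asarray(mean, dtype=float)
            sd = np.zeros(n) if sd is None else np.asarray(sd, dtype=float)
        else:
            prob = np.full(n, np.nan)
            mean = np.full(n, np.nan)
            sd = np.zeros(n)
            for i, (a, c, d) in enumerate(self._keys):
                p, m, s = spec.func(AgeDevGroup(int(a), int(c), int(d), 0))
                if p is not None:
                    prob[i] = p
                else:
                    mean[i] = m
                    sd[i] = 0.0 if s is None else s
        out = np.empty(n, dtype=float)
        fixed = ~np.isnan(prob)
        if fixed.any():
            p = prob[fixed]
            if np.any((p < 0) | (p > 1)):
                raise ParameterError("per-stratum probabilities must be in [0,1]")
            out[fixed] = p  # memoryless: the hazard is the probability itself
        rest = ~fixed
        if rest.any():
            # Evaluate each distinct (mean, sd) lifetime once, vectorised
            # over the step counters of the strata that share it.  The pair
            # is folded into one complex number so uniqueness is 1-D.
            pairs = mean[rest] + 1j * sd[rest]
            uniq, inverse = np.unique(pairs, return_inverse=True)
            sub = np.empty(rest.sum(), dtype=float)
            tsub = taus[rest]
            for u, ms in enumerate(uniq):
                m, s = ms.real, ms.imag
                params = ProcessSpec(mean=m, sd=s).params(self.family)
                sel = inverse == u
                sub[sel] = np.asarray(hazard_step(params, tsub[sel]), dtype=float).reshape(-1)
            out[rest] = sub
        return out

    # -- dynamics -----------------------------------------------------------

    def iterate(self, dev: ProcessSpec = NOP, death: ProcessSpec = NOP,
                pause: bool = False) -> IterationResult:
        """Apply one step of coupled survival and development.

        Death is applied first (at the age counter), then development among
        the survivors (at the development counter); an individual cannot both
        die and complete development within one step.  Survivors age by one
        step and completing strata move to the devtable with the cycle
        counter incremented and development reset -- unless ``pause`` is set,
        in which case all counters are frozen (the perturb semantics used for
        interventions and migration).
        """
        size_before = self.size
        if len(self._num) == 0:
            self.dead = 0 if self.stochastic else 0.0
            self.developed = 0 if self.stochastic else 0.0
            self.devtable = StratumTable.empty(self.stochastic)
            return IterationResult(self.size, self.dead, self.developed, self.devtable)

        q = self._hazards(death, self._keys[:, 0])  # death at age counter
        g = self._hazards(dev, self._keys[:, 2])    # development at development counter

        n = self._num
        if self.stochastic:
            dead = self.rng.binomial(n, q)
            completing = self.rng.binomial(n - dead, g)
        else:
            dead = n * q
            completing = (n - dead) * g
        remaining = n - dead - completing

        if pause:
            surv_keys = self._keys
            dev_keys = self._keys
        else:
            surv_keys = self._keys + np.array([1, 0, 1], dtype=np.int64)
            dev_keys = (self._keys + np.array([1, 1, 0], dtype=np.int64))
            dev_keys[:, 2] = 0  # development resets on completion

        live = remaining > 0
        comp = completing > 0
        dk, dn = self._merge(dev_keys[comp], completing[comp].astype(self._dtype))
        self.devtable = StratumTable(dk, dn)
        self._store(surv_keys[live], remaining[live])

        self.dead = dead.sum() if self.stochastic else float(dead.sum())
        self.developed = completing.sum() if self.stochastic else float(completing.sum())
        if self.stochastic:
            self.dead, self.developed = int(self.dead), int(self.developed)
            assert size_before == self.size + self.dead + self.developed
        else:
            gap = abs(size_before - (self.size + self.dead + self.developed))
            allowance = 1e-9 * max(1.0, size_before) + self._pruned_mass
            assert gap <= allowance, "conservation violated"
        return IterationResult(self.size, self.dead, self.developed, self.devtable)

    def perturb(self, dev: ProcessSpec = NOP, death: ProcessSpec = NOP) -> IterationResult:
        """One step with all counters frozen: ``iterate(..., pause=True)``.

        Models instantaneous interventions (``death``: cull a fraction) and
        migration (``dev``: select individuals into the devtable, keeping a
        detailed record of their age and stage, without ageing anyone).
        """
        return self.iterate(dev=dev, death=death, pause=True)

    # -- snapshots ----------------------------------------------------------

    def snapshot(self) -> pd.DataFrame:
        """Stratum table (age, devcycle, development, number), key-sorted."""
        return StratumTable(self._keys, self._num).to_frame()

    def write_snapshot(self, path) -> None:
        """Write the stratum table as headered TSV (full-precision numbers)."""
        df = self.snapshot()
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    def read_snapshot(self, path) -> None:
        """Replace the population contents with a TSV snapshot."""
        df = pd.read_csv(path, sep="\t")
        expected = list(_KEY_COLS) + ["number"]
        if list(df.columns) != expected:
            raise ValueError(f"snapshot must have columns {expected}, got {list(df.columns)}")
        self.empty()
        keys = df[list(_KEY_COLS)].to_numpy(dtype=np.int64)
        nums = df["number"].to_numpy(dtype=self._dtype)
        if np.any(nums < 0):
            raise ValueError("snapshot numbers must be non-negative")
        keys, nums = self._merge(keys, nums)
        self._store(keys, nums)
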