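"""Demographic scenarios, priors and parameter sampling.

Four competing histories for three extant wolf populations (pop1 = Italian
peninsula, pop2 = Iberian peninsula, pop3 = Dinaric region) are represented:
the populations split from a common ancestor either simultaneously
(scenarios 1 and 2) or sequentially (scenarios 3 and 4), and either passed
through a bottleneck after the split (scenarios 2 and 4) or did not
(scenarios 1 and 3).

Time is measured in generations before present, sizes are diploid effective
population sizes.  A bottleneck is parameterised backwards in time: the
population has its current (post-bottleneck) size ``Ni`` on ``[0, db)`` and
its larger pre-bottleneck size ``Nib`` on ``[db, t_split)``; ``db`` is
therefore both the onset of the reduced phase (looking back) and its
duration, which matches the convention used to convert the bottleneck time
to years.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "PriorSpec",
    "DemographicScenario",
    "ParameterDraw",
    "EpochPlan",
    "SCENARIOS",
    "DEFAULT_PRIORS",
    "default_priors",
    "ConfigurationError",
    "required_symbols",
    "sample_parameters",
    "build_epochs",
    "load_config",
]

#: population labels, in simulation order
POP_LABELS = ("WIT", "WIB", "WDIN")

#: parameter symbols in canonical column order
ALL_SYMBOLS = (
    "N1", "N2", "N3", "N1b", "N2b", "N3b", "NA",
    "t1", "t2", "db", "mu_mic", "p_mic", "sni_mic",
)


class ConfigurationError(ValueError):
    """Raised for inconsistent scenario/prior configuration."""


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior for one scalar parameter.

    Parameters
    ----------
    name : str
        Parameter symbol (one of :data:`ALL_SYMBOLS`).
    low, high : float
        Interval bounds, ``low <= high``.  ``low == high`` is a point prior.
    kind : str
        Only ``"uniform"`` is supported.
    """

    name: str
    low: float
    high: float
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind != "uniform":
            raise ConfigurationError(f"unsupported prior kind {self.kind!r}")
        if not (self.low <= self.high):
            raise ConfigurationError(
                f"prior {self.name}: low={self.low} > high={self.high}"
            )

    def sample(self, rng: np.random.Generator, size=None):
        if self.low == self.high:
            return self.low if size is None else np.full(size, self.low)
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class DemographicScenario:
    """One of the four competing demographic histories."""

    id: int
    split_mode: str  # "simultaneous" | "sequential"
    bottleneck: bool
    pop_labels: tuple = POP_LABELS

    _TABLE = {
        1: ("simultaneous", False),
        2: ("simultaneous", True),
        3: ("sequential", False),
        4: ("sequential", True),
    }

    def __post_init__(self) -> None:
        expected = self._TABLE.get(self.id)
        if expected is None:
            raise ConfigurationError(f"scenario id must be 1..4, got {self.id}")
        if (self.split_mode, self.bottleneck) != expected:
            raise ConfigurationError(
                f"scenario {self.id} must be split_mode={expected[0]!r}, "
                f"bottleneck={expected[1]}"
            )

    @classmethod
    def from_id(cls, scenario_id: int) -> "DemographicScenario":
        mode, bn = cls._TABLE[int(scenario_id)]
        return cls(int(scenario_id), mode, bn)

    @property
    def sequential(self) -> bool:
        return self.split_mode == "sequential"


#: the full scenario set, by id
SCENARIOS = {i: DemographicScenario.from_id(i) for i in (1, 2, 3, 4)}


@dataclass
class ParameterDraw:
    """One sampled parameter vector.

    Sizes are diploid; times are generations before present; ``mu_mic`` is
    the mean microsatellite mutation rate per locus per generation,
    ``p_mic`` the geometric step-size parameter of the generalised stepwise
    model, and ``sni_mic`` the single-nucleotide indel rate.  Symbols a
    scenario does not use are ``nan``.
    """

    N1: float
    N2: float
    N3: float
    NA: float
    t1: float
    mu_mic: float
    p_mic: float
    sni_mic: float
    N1b: float = math.nan
    N2b: float = math.nan
    N3b: float = math.nan
    t2: float = math.nan
    db: float = math.nan

    def as_dict(self) -> dict:
        return {s: getattr(self, s) for s in ALL_SYMBOLS}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterDraw":
        return cls(**{k: float(v) for k, v in d.items() if k in ALL_SYMBOLS})

    def validate(self, scenario: DemographicScenario) -> None:
        """Check the scenario's ordering and positivity constraints."""
        for s in ("N1", "N2", "N3", "NA"):
            if not getattr(self, s) >= 1:
                raise ConfigurationError(f"{s} must be >= 1")
        if not self.t1 > 0:
            raise ConfigurationError("t1 must be > 0")
        if scenario.bottleneck:
            for s in ("N1b", "N2b", "N3b"):
                if not getattr(self, s) >= 1:
                    raise ConfigurationError(f"{s} must be >= 1 (bottleneck scenario)")
            if not self.db < self.t1:
                raise ConfigurationError("db must be < t1")
            if not self.db > 0:
                raise ConfigurationError("db must be > 0")
        if scenario.sequential and not self.t1 < self.t2:
            raise ConfigurationError("sequential scenarios require t1 < t2")


def default_priors() -> dict:
    """Default uniform priors.

    Chosen wide enough to contain the posterior 90% intervals reported for
    the wolf analysis; override any of them via configuration.
    """
    spec = {
        "N1": (100, 10_000), "N2": (100, 10_000), "N3": (100, 10_000),
        "NA": (100, 10_000),
        "N1b": (100, 30_000), "N2b": (100, 30_000), "N3b": (100, 30_000),
        "t1": (100, 10_000), "t2": (100, 10_000), "db": (100, 10_000),
        "mu_mic": (1e-4, 1e-3), "p_mic": (0.1, 0.3), "sni_mic": (1e-8, 1e-5),
    }
    return {k: PriorSpec(k, float(lo), float(hi)) for k, (lo, hi) in spec.items()}


DEFAULT_PRIORS = default_priors()


def required_symbols(scenario: DemographicScenario) -> tuple:
    """Parameter symbols a scenario actually uses."""
    syms = ["N1", "N2", "N3", "NA", "t1", "mu_mic", "p_mic", "sni_mic"]
    if scenario.bottleneck:
        syms += ["N1b", "N2b", "N3b", "db"]
    if scenario.sequential:
        syms.append("t2")
    return tuple(s for s in ALL_SYMBOLS if s in syms)


_MAX_RESAMPLE = 10_000


def _check_feasible(priors, scenario) -> None:
    if scenario.bottleneck and priors["db"].low >= priors["t1"].high:
        raise ConfigurationError("infeasible constraint: db.low >= t1.high")
    if scenario.sequential and priors["t1"].low >= priors["t2"].high:
        raise ConfigurationError("infeasible constraint: t1.low >= t2.high")


def sample_parameters(
    priors: Mapping[str, PriorSpec],
    scenario: DemographicScenario,
    rng: np.random.Generator,
) -> ParameterDraw:
    """Draw one parameter vector from the priors, honouring constraints.

    Each component is uniform on its prior interval; the ordering
    constraints ``db < t1`` (bottleneck scenarios) and ``t1 < t2``
    (sequential scenarios) are enforced by jointly resampling the
    constrained pair, which leaves each marginal uniform on the accepted
    region.
    """
    needed = required_symbols(scenario)
    missing = [s for s in needed if s not in priors]
    if missing:
        raise ConfigurationError(f"missing prior(s) for {missing}")
    _check_feasible(priors, scenario)

    vals = {s: float(priors[s].sample(rng)) for s in needed}

    constrained = []
    if scenario.bottleneck:
        constrained.append(("db", "t1"))
    if scenario.sequential:
        constrained.append(("t1", "t2"))
    if constrained:
        resample = sorted({s for pair in constrained for s in pair})
        degenerate = all(priors[s].low == priors[s].high for s in resample)

        def ok() -> bool:
            return all(vals[lo] < vals[hi] for lo, hi in constrained)

        if degenerate and not ok():
            raise ConfigurationError(
                "point priors violate ordering constraints "
                + str(constrained)
            )
        if not degenerate:
            for _ in range(_MAX_RESAMPLE):
                if ok():
                    break
                for s in resample:
                    vals[s] = float(priors[s].sample(rng))
            else:
                raise ConfigurationError(
                    f"could not satisfy ordering constraints {constrained}"
                )

    return ParameterDraw.from_dict(vals)


# ---------------------------------------------------------------------------
# Epoch plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """A demographic event, backwards in time.

    ``kind`` is ``"resize"`` (population ``pop`` takes size ``size`` from
    ``time`` onward, looking back) or ``"merge"`` (lineages of ``pop`` move
    into population ``dest``).
    """

    time: float
    kind: str
    pop: int
    dest: int = -1
    size: float = math.nan


@dataclass
class EpochPlan:
    """Executable piecewise-constant demography for the coalescent engine.

    ``initial_sizes[i]`` is population *i*'s diploid size on the most recent
    epoch; ``events`` are sorted by time (merges before resizes at ties) and
    must leave exactly one lineage-bearing population after the last merge.
    """

    initial_sizes: np.ndarray
    events: list = field(default_factory=list)

    @property
    def n_pops(self) -> int:
        return len(self.initial_sizes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EpochPlan)
            and np.array_equal(self.initial_sizes, other.initial_sizes)
            and self.events == other.events
        )

    def validate(self) -> None:
        """Check temporal ordering, positivity, and a single final ancestor."""
        if np.any(np.asarray(self.initial_sizes) < 1):
            raise ConfigurationError("initial sizes must be >= 1")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ConfigurationError("event times must be >= 0")
        if times != sorted(times):
            raise ConfigurationError("events must be sorted by time")
        alive = [True] * self.n_pops
        for e in self.events:
            if e.kind == "merge":
                if not alive[e.pop] or not alive[e.dest]:
                    raise ConfigurationError("merge involving a dead population")
                alive[e.pop] = False
            elif e.kind == "resize":
                if not alive[e.pop]:
                    raise ConfigurationError("resize of a dead population")
                if not e.size >= 1:
                    raise ConfigurationError("resize to size < 1")
            else:
                raise ConfigurationError(f"unknown event kind {e.kind!r}")
        if sum(alive) != 1:
            raise ConfigurationError(
                f"{sum(alive)} populations remain after the final merge; expected 1"
            )

    def epochs(self) -> dict:
        """Per-population size epochs ``[(start, end, size), ...]``.

        The last epoch of the final ancestral population is open-ended
        (``end = inf``); used for display and round-trip checks.
        """
        out = {p: [] for p in range(self.n_pops)}
        cur = {p: (0.0, float(self.initial_sizes[p])) for p in range(self.n_pops)}
        for e in self.events:
            if e.pop not in cur:
                continue
            if e.kind == "resize":
                start, size = cur[e.pop]
                if e.time > start:
                    out[e.pop].append((start, e.time, size))
                cur[e.pop] = (e.time, float(e.size))
            elif e.kind == "merge":
                start, size = cur[e.pop]
                if e.time > start:
                    out[e.pop].append((start, e.time, size))
                del cur[e.pop]
        for p, (start, size) in cur.items():
            out[p].append((start, math.inf, size))
        return out

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "initial_sizes": [float(x) for x in self.initial_sizes],
            "events": [dataclasses.asdict(e) for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EpochPlan":
        return cls(
            initial_sizes=np.asarray(d["initial_sizes"], dtype=float),
            events=[Event(**e) for e in d["events"]],
        )


def build_epochs(scenario: DemographicScenario, draw: ParameterDraw) -> EpochPlan:
    """Translate a scenario plus a parameter draw into an :class:`EpochPlan`.

    Simultaneous scenarios: all three populations merge at ``t1`` into an
    ancestor of size ``NA``.  Sequential scenarios: pop2 and pop3 merge at
    ``t1`` (their ancestor takes size ``NA``), and that ancestor merges with
    pop1 at ``t2``.  Under a bottleneck, population *i* has size ``Ni`` on
    ``[0, db)`` and ``Nib`` from ``db`` until its merge.
    """
    draw.validate(scenario)
    sizes = np.array([draw.N1, draw.N2, draw.N3], dtype=float)
    ev: list = []
    if scenario.bottleneck:
        pre = (draw.N1b, draw.N2b, draw.N3b)
        for p in range(3):
            ev.append(Event(time=float(draw.db), kind="resize", pop=p, size=float(pre[p])))
    if scenario.sequential:
        ev.append(Event(time=float(draw.t1), kind="merge", pop=2, dest=1))
        ev.append(Event(time=float(draw.t1), kind="resize", pop=1, size=float(draw.NA)))
        ev.append(Event(time=float(draw.t2), kind="merge", pop=1, dest=0))
        ev.append(Event(time=float(draw.t2), kind="resize", pop=0, size=float(draw.NA)))
    else:
        ev.append(Event(time=float(draw.t1), kind="merge", pop=1, dest=0))
        ev.append(Event(time=float(draw.t1), kind="merge", pop=2, dest=0))
        ev.append(Event(time=float(draw.t1), kind="resize", pop=0, size=float(draw.NA)))
    ev.sort(key=lambda e: (e.time, 0 if e.kind == "merge" else 1))
    plan = EpochPlan(initial_sizes=sizes, events=ev)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Read a YAML/JSON configuration file.

    Recognised top-level keys: ``scenarios`` (list of ids), ``priors``
    (mapping symbol -> {low, high}), and any run settings, which are
    returned untouched.  Returns a dict with ``scenarios`` replaced by
    :class:`DemographicScenario` objects and ``priors`` by
    :class:`PriorSpec` objects merged over the defaults.
    """
    with open(path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text) or {}
    out = dict(cfg)
    ids = cfg.get("scenarios", [1, 2, 3, 4])
    out["scenarios"] = [DemographicScenario.from_id(i) for i in ids]
    priors = default_priors()
    for sym, bounds in (cfg.get("priors") or {}).items():
        if sym not in ALL_SYMBOLS:
            raise ConfigurationError(f"unknown parameter symbol {sym!r}")
        if isinstance(bounds, Mapping):
            lo, hi = bounds["low"], bounds["high"]
        else:
            lo, hi = bounds
        priors[sym] = PriorSpec(sym, float(lo), float(hi))
    out["priors"] = priors
    return out


def dump_scenario_draw(scenario: DemographicScenario, draw: ParameterDraw) -> str:
    """Serialise a scenario + draw pair to JSON (round-trips exactly)."""
    return json.dumps({"scenario": scenario.id, "draw": draw.as_dict()})


def load_scenario_draw(text: str):
    d = json.loads(text)
    return SCENARIOS[d["scenario"]], ParameterDraw.from_dict(d["draw"])
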