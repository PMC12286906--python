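"""Domain types, validation, and configuration I/O for the dependence model.

The model describes a cohort of people with dementia distributed over three
alive dependence states (defined by Bristol Activities of Daily Living Scale
bands: low 0-14, moderate 15-29, high 30+) plus an absorbing dead state.
Everything needed to run the model -- entry distribution, per-cycle transition
probabilities, per-cycle care costs, state utilities, and accounting
conventions -- lives in a :class:`ModelParameters` bundle, which can be read
from and written to a YAML configuration.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DependenceLevel",
    "ALIVE_LEVELS",
    "STATE_ORDER",
    "StateDistribution",
    "TransitionModel",
    "CostSet",
    "UtilitySet",
    "ModelSettings",
    "InterventionSpec",
    "ModelParameters",
    "ParameterError",
    "validate_parameters",
    "load_config",
    "write_config",
    "base_case_parameters",
    "default_config_path",
]

_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """Raised when one or more model-parameter invariants are violated.

    ``violations`` lists every failed invariant with the offending field,
    so a bad configuration is reported in full rather than one error at a
    time.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class DependenceLevel(enum.Enum):
    """The four health states: three dependence bands and the dead state."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    DEAD = "dead"

    @property
    def is_alive(self) -> bool:
        return self is not DependenceLevel.DEAD


STATE_ORDER: tuple[DependenceLevel, ...] = (
    DependenceLevel.LOW,
    DependenceLevel.MODERATE,
    DependenceLevel.HIGH,
    DependenceLevel.DEAD,
)
ALIVE_LEVELS: tuple[DependenceLevel, ...] = STATE_ORDER[:3]

# EQ-5D-5L index values for England lie in this closed interval.
UTILITY_FLOOR = -0.594
UTILITY_CEIL = 1.0


@dataclass(frozen=True)
class StateDistribution:
    """Occupancy proportions over (low, moderate, high, dead).

    Proportions must be non-negative and sum to one to within 1e-12.
    """

    low: float
    moderate: float
    high: float
    dead: float

    def as_array(self) -> np.ndarray:
        return np.array([self.low, self.moderate, self.high, self.dead], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateDistribution":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ParameterError([f"state distribution must have 4 entries, got shape {a.shape}"])
        return cls(*a.tolist())

    def validate(self) -> list[str]:
        errs = []
        a = self.as_array()
        if (a < 0).any():
            bad = [STATE_ORDER[i].value for i in np.nonzero(a < 0)[0]]
            errs.append(f"state distribution has negative proportion(s) for {bad}")
        if abs(a.sum() - 1.0) > _SUM_TOL:
            errs.append(f"state distribution sum != 1 (got {a.sum()!r})")
        return errs

    def __getitem__(self, level: DependenceLevel) -> float:
        return float(self.as_array()[STATE_ORDER.index(level)])


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle (3-month) transition probabilities.

    Progression is stepwise and irreversible: low can only move to moderate,
    moderate to high, and any alive state can die.  The dead state is
    absorbing.
    """

    p_low_to_mod: float
    p_mod_to_high: float
    p_death_low: float
    p_death_mod: float
    p_death_high: float

    def validate(self) -> list[str]:
        errs = []
        for name in (
            "p_low_to_mod",
            "p_mod_to_high",
            "p_death_low",
            "p_death_mod",
            "p_death_high",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name} not in [0, 1] (got {v!r})")
        if self.p_low_to_mod + self.p_death_low > 1.0:
            errs.append(
                "low-state row exceeds 1: "
                f"p_low_to_mod + p_death_low = {self.p_low_to_mod + self.p_death_low!r}"
            )
        if self.p_mod_to_high + self.p_death_mod > 1.0:
            errs.append(
                "moderate-state row exceeds 1: "
                f"p_mod_to_high + p_death_mod = {self.p_mod_to_high + self.p_death_mod!r}"
            )
        return errs


@dataclass(frozen=True)
class CostSet:
    """Per-cycle (3-month) costs in GBP, cost-year 2019/20.

    ``care`` covers primary, secondary and social care by alive state;
    ``death_event_cost`` is the one-off non-elective hospital admission that
    precedes each death.  ``informal_care`` is an optional per-state add-on
    used only under the societal perspective; no default values are packaged.
    """

    care: Mapping[DependenceLevel, float]
    death_event_cost: float
    informal_care: Mapping[DependenceLevel, float] | None = None

    def care_vector(self) -> np.ndarray:
        return np.array([self.care[s] for s in ALIVE_LEVELS] + [0.0])

    def informal_vector(self) -> np.ndarray:
        if self.informal_care is None:
            raise ParameterError(["informal_care costs not configured (required for societal perspective)"])
        return np.array([self.informal_care[s] for s in ALIVE_LEVELS] + [0.0])

    def validate(self) -> list[str]:
        errs = []
        for s in ALIVE_LEVELS:
            if s not in self.care:
                errs.append(f"care cost missing for state {s.value}")
            elif self.care[s] < 0:
                errs.append(f"care cost for {s.value} is negative ({self.care[s]!r})")
        if self.death_event_cost < 0:
            errs.append(f"death_event_cost is negative ({self.death_event_cost!r})")
        if self.informal_care is not None:
            for s in ALIVE_LEVELS:
                if s not in self.informal_care:
                    errs.append(f"informal care cost missing for state {s.value}")
                elif self.informal_care[s] < 0:
                    errs.append(f"informal care cost for {s.value} is negative")
        return errs


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility values plus an age-based decrement schedule.

    Utility of the dead state is fixed at zero.  ``decrement_schedule`` maps
    age (years) to an additive utility decrement applied to every alive state
    once the cohort reaches that age; between listed ages the decrement is
    piecewise-constant (the value at the largest listed age not exceeding the
    current age), and zero below the first listed age.  The default schedule
    is empty, i.e. zero decrement at all ages.
    """

    values: Mapping[DependenceLevel, float]
    decrement_schedule: Mapping[float, float] = field(default_factory=dict)

    def utility_vector(self) -> np.ndarray:
        return np.array([self.values[s] for s in ALIVE_LEVELS] + [0.0])

    def decrement(self, age: float) -> float:
        dec = 0.0
        for a in sorted(self.decrement_schedule):
            if age >= a:
                dec = float(self.decrement_schedule[a])
            else:
                break
        return dec

    def validate(self) -> list[str]:
        errs = []
        for s in ALIVE_LEVELS:
            if s not in self.values:
                errs.append(f"utility value missing for state {s.value}")
            elif not (UTILITY_FLOOR <= self.values[s] <= UTILITY_CEIL):
                errs.append(
                    f"utility for {s.value} outside [{UTILITY_FLOOR}, {UTILITY_CEIL}] "
                    f"({self.values[s]!r})"
                )
        if self.values.get(DependenceLevel.DEAD, 0.0) != 0.0:
            errs.append("utility of DEAD must be exactly 0")
        for a, d in self.decrement_schedule.items():
            if d < 0:
                errs.append(f"decrement at age {a} is negative ({d!r})")
        return errs


#: Discounting conventions supported by the engine.
#:
#: ``cycle_rate_annual_step``
#:     The annual rate is converted to its per-cycle equivalent,
#:     ``(1+r)**cycle_length - 1``, and compounded once per completed model
#:     year: factor ``(1+r)**(-y*cycle_length)`` for a cycle in year ``y``.
#:     This is the calibrated default; it reproduces the published base-case
#:     results this package is validated against (see docs/methods.md).
#: ``annual_step``
#:     Textbook annual-step discounting, ``(1+r)**(-y)``.
#: ``per_cycle``
#:     Continuous per-cycle compounding, ``(1+r)**(-t*cycle_length)``.
DISCOUNTING_MODES = ("cycle_rate_annual_step", "annual_step", "per_cycle")


@dataclass(frozen=True)
class ModelSettings:
    """Run conventions: horizon, cycle length, discounting and accounting flags.

    The four accounting flags (``discounting``, ``include_terminal_cycle``,
    ``half_cycle_correction``, ``death_cost_schedule``) plus
    ``intervention_cost_alive_only`` encode conventions that a published
    cohort model may leave implicit; their defaults here were fixed by
    calibration against the base-case anchor values (see the ``calibrate``
    CLI subcommand and docs/methods.md).
    """

    horizon_years: float = 10.0
    cycle_length_years: float = 0.25
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    entry_age: float = 80.0
    cohort_size: int = 1000
    first_year_undiscounted: bool = True
    discounting: str = "cycle_rate_annual_step"
    include_terminal_cycle: bool = True
    half_cycle_correction: bool = False
    intervention_cost_alive_only: bool = False
    death_cost_schedule: str = "reference"  # or "arm"

    @property
    def n_cycles(self) -> int:
        n = self.horizon_years / self.cycle_length_years
        return int(round(n))

    @property
    def cycles_per_year(self) -> int:
        return int(round(1.0 / self.cycle_length_years))

    def validate(self) -> list[str]:
        errs = []
        if self.cycle_length_years <= 0:
            errs.append(f"cycle_length_years must be > 0 (got {self.cycle_length_years!r})")
        else:
            n = self.horizon_years / self.cycle_length_years
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                errs.append(
                    "horizon_years / cycle_length_years must be a positive integer "
                    f"(got {n!r})"
                )
        for name in ("discount_rate_costs", "discount_rate_qalys"):
            if getattr(self, name) < 0:
                errs.append(f"{name} is negative ({getattr(self, name)!r})")
        if self.discounting not in DISCOUNTING_MODES:
            errs.append(f"unknown discounting mode {self.discounting!r}; expected one of {DISCOUNTING_MODES}")
        if self.death_cost_schedule not in ("reference", "arm"):
            errs.append(f"death_cost_schedule must be 'reference' or 'arm' (got {self.death_cost_schedule!r})")
        if self.cohort_size < 1:
            errs.append(f"cohort_size must be >= 1 (got {self.cohort_size!r})")
        return errs


@dataclass(frozen=True)
class InterventionSpec:
    """A hypothetical independence-preserving intervention.

    The intervention acts once, at model entry, by moving a fraction ``effect``
    (the sample-level effect *e*) of each donor state's occupancy one
    dependence level down: moderate to low, and (unless ``subgroup_only``)
    high to moderate.  ``relative=True`` (the default) means *e* scales the
    donor state's occupancy; ``relative=False`` means *e* is an absolute share
    of the whole sample moved out of each donor state.
    """

    per_person_cost: float = 570.0
    effect: float = 0.025
    subgroup_only: bool = False
    relative: bool = True

    def validate(self) -> list[str]:
        errs = []
        if not (0.0 <= self.effect <= 1.0):
            errs.append(f"intervention effect not in [0, 1] (got {self.effect!r})")
        if self.per_person_cost < 0:
            errs.append(f"intervention per_person_cost is negative ({self.per_person_cost!r})")
        return errs


@dataclass(frozen=True)
class ModelParameters:
    """Everything needed to run the cohort model once."""

    entry_distribution: StateDistribution
    transitions: TransitionModel
    costs: CostSet
    utilities: UtilitySet
    settings: ModelSettings = field(default_factory=ModelSettings)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Validate every component invariant; return the bundle unchanged if valid.

    Raises :class:`ParameterError` listing *all* violations, not just the
    first one found.
    """
    errs: list[str] = []
    errs += params.entry_distribution.validate()
    errs += params.transitions.validate()
    errs += params.costs.validate()
    errs += params.utilities.validate()
    errs += params.settings.validate()
    if errs:
        raise ParameterError(errs)
    return params


# --------------------------------------------------------------------------
# configuration I/O

_REQUIRED_KEYS = ("entry_distribution", "transitions", "costs", "utilities")
_KNOWN_TOP_KEYS = _REQUIRED_KEYS + ("settings", "intervention", "scenarios", "calibration")


def _level_map(d: Mapping[str, float]) -> dict[DependenceLevel, float]:
    return {DependenceLevel(k): float(v) for k, v in d.items()}


def params_from_dict(cfg: Mapping) -> ModelParameters:
    """Build a :class:`ModelParameters` bundle from a parsed configuration dict."""
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ParameterError([f"configuration missing required key {key!r}"])
    unknown = [k for k in cfg if k not in _KNOWN_TOP_KEYS]
    if unknown:
        warnings.warn(f"ignoring unknown configuration keys: {unknown}", stacklevel=2)

    ed = cfg["entry_distribution"]
    entry = StateDistribution(
        low=float(ed["low"]),
        moderate=float(ed["moderate"]),
        high=float(ed["high"]),
        dead=float(ed["dead"]),
    )
    tr = cfg["transitions"]
    transitions = TransitionModel(
        p_low_to_mod=float(tr["low_to_moderate"]),
        p_mod_to_high=float(tr["moderate_to_high"]),
        p_death_low=float(tr["death_low"]),
        p_death_mod=float(tr["death_moderate"]),
        p_death_high=float(tr["death_high"]),
    )
    cc = cfg["costs"]
    informal = cc.get("informal_care")
    costs = CostSet(
        care=_level_map(cc["care"]),
        death_event_cost=float(cc["death_event"]),
        informal_care=_level_map(informal) if informal else None,
    )
    uu = dict(cfg["utilities"])
    schedule = uu.pop("decrement_schedule", None) or {}
    utilities = UtilitySet(
        values={**_level_map(uu), DependenceLevel.DEAD: 0.0},
        decrement_schedule={float(a): float(d) for a, d in schedule.items()},
    )
    settings = ModelSettings(**cfg.get("settings", {}))
    return validate_parameters(
        ModelParameters(entry, transitions, costs, utilities, settings)
    )


def params_to_dict(params: ModelParameters) -> dict:
    """Inverse of :func:`params_from_dict` (round-trips on valid bundles)."""
    s = params.settings
    out = {
        "entry_distribution": {
            "low": params.entry_distribution.low,
            "moderate": params.entry_distribution.moderate,
            "high": params.entry_distribution.high,
            "dead": params.entry_distribution.dead,
        },
        "transitions": {
            "low_to_moderate": params.transitions.p_low_to_mod,
            "moderate_to_high": params.transitions.p_mod_to_high,
            "death_low": params.transitions.p_death_low,
            "death_moderate": params.transitions.p_death_mod,
            "death_high": params.transitions.p_death_high,
        },
        "costs": {
            "care": {k.value: v for k, v in params.costs.care.items()},
            "death_event": params.costs.death_event_cost,
        },
        "utilities": {
            **{k.value: v for k, v in params.utilities.values.items() if k.is_alive},
            "decrement_schedule": dict(params.utilities.decrement_schedule),
        },
        "settings": {
            "horizon_years": s.horizon_years,
            "cycle_length_years": s.cycle_length_years,
            "discount_rate_costs": s.discount_rate_costs,
            "discount_rate_qalys": s.discount_rate_qalys,
            "entry_age": s.entry_age,
            "cohort_size": s.cohort_size,
            "first_year_undiscounted": s.first_year_undiscounted,
            "discounting": s.discounting,
            "include_terminal_cycle": s.include_terminal_cycle,
            "half_cycle_correction": s.half_cycle_correction,
            "intervention_cost_alive_only": s.intervention_cost_alive_only,
            "death_cost_schedule": s.death_cost_schedule,
        },
    }
    if params.costs.informal_care is not None:
        out["costs"]["informal_care"] = {
            k.value: v for k, v in params.costs.informal_care.items()
        }
    return out


def load_config(path: str | Path) -> tuple[ModelParameters, dict]:
    """Load a YAML configuration.

    Returns ``(params, extras)`` where ``extras`` holds the optional
    ``intervention``, ``scenarios`` and ``calibration`` sections verbatim.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError([f"configuration file {path} did not parse to a mapping"])
    params = params_from_dict(cfg)
    extras = {k: cfg[k] for k in ("intervention", "scenarios", "calibration") if k in cfg}
    return params, extras


def write_config(params: ModelParameters, path: str | Path, extras: Mapping | None = None) -> None:
    """Write a bundle (plus optional extra sections) as YAML; inverse of load_config."""
    out = params_to_dict(params)
    if extras:
        out.update(dict(extras))
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the packaged base-case configuration."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def base_case_parameters() -> ModelParameters:
    """The base-case parameter bundle from the packaged configuration."""
    params, _ = load_config(default_config_path())
    return params
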