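"""Markov cohort engine: trace propagation, discounting, cost/QALY accounting.

The cohort occupancy vector is propagated through a fixed 4x4 per-cycle
transition matrix.  A run over ``n`` cycles produces ``n+1`` occupancy
points (entry state plus one per transition); by default all ``n+1`` points
accrue a cycle of costs and utility (``include_terminal_cycle=True``), with
no half-cycle correction.  Death-event (hospital admission) costs attach to
the cycle index at which each death completes, and are included only when
that index is among the valued points.  See docs/methods.md for how these
conventions were fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    STATE_ORDER,
    CostSet,
    InterventionSpec,
    ModelParameters,
    ModelSettings,
    ParameterError,
    StateDistribution,
    TransitionModel,
    UtilitySet,
    validate_parameters,
)

__all__ = [
    "build_transition_matrix",
    "CohortTrace",
    "run_cohort",
    "discount_factor",
    "accumulate_costs",
    "accumulate_qalys",
    "PersonLevelResult",
    "run_model",
    "microsimulate",
    "trace_to_frame",
]

_ROW_TOL = 1e-12


def build_transition_matrix(tm: TransitionModel) -> np.ndarray:
    """Assemble the 4x4 per-cycle transition matrix (rows = from-state).

    State order is (LOW, MODERATE, HIGH, DEAD).  Structural zeros encode the
    stepwise, irreversible progression: no low->high jump within a cycle, no
    backward moves, and DEAD is absorbing.
    """
    errs = tm.validate()
    if errs:
        raise ParameterError(errs)
    p = np.array(
        [
            [1.0 - tm.p_low_to_mod - tm.p_death_low, tm.p_low_to_mod, 0.0, tm.p_death_low],
            [0.0, 1.0 - tm.p_mod_to_high - tm.p_death_mod, tm.p_mod_to_high, tm.p_death_mod],
            [0.0, 0.0, 1.0 - tm.p_death_high, tm.p_death_high],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    if (np.diag(p) < 0).any():
        raise ParameterError(["transition probabilities incompatible: negative stay probability"])
    assert np.allclose(p.sum(axis=1), 1.0, atol=_ROW_TOL)
    return p


@dataclass(frozen=True)
class CohortTrace:
    """Cohort occupancy per cycle plus the per-cycle flow into the dead state.

    ``occupancy`` has shape ``(n_cycles + 1, 4)``; row ``t`` is the
    distribution after ``t`` transitions (row 0 is the entry distribution).
    ``new_deaths[k]`` is the proportion of the cohort dying during cycle
    ``k`` (i.e. between occupancy rows ``k`` and ``k+1``).
    """

    occupancy: np.ndarray
    new_deaths: np.ndarray

    def __post_init__(self):
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError(["cohort trace occupancy does not sum to 1 at every cycle"])
        if (occ < -1e-12).any():
            raise ParameterError(["cohort trace has negative occupancy"])
        if (np.diff(occ[:, 3]) < -1e-12).any():
            raise ParameterError(["dead occupancy must be non-decreasing"])

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, 3]


def run_cohort(
    entry: StateDistribution, matrix: np.ndarray, settings: ModelSettings
) -> CohortTrace:
    """Propagate the entry distribution through ``settings.n_cycles`` cycles."""
    errs = entry.validate()
    if errs:
        raise ParameterError(errs)
    n = settings.n_cycles
    occ = np.empty((n + 1, 4))
    occ[0] = entry.as_array()
    for t in range(1, n + 1):
        occ[t] = occ[t - 1] @ matrix
    return CohortTrace(occupancy=occ, new_deaths=np.diff(occ[:, 3]))


def discount_factor(t: int, annual_rate: float, settings: ModelSettings) -> float:
    """Discount factor for cycle index ``t`` under the configured convention.

    All conventions leave the first model year undiscounted when
    ``settings.first_year_undiscounted`` is set (amounts are discounted only
    once accrued beyond year one).  ``y`` below is the completed-year index
    ``floor(t * cycle_length_years)``.

    - ``cycle_rate_annual_step`` (calibrated default): ``(1+r)**(-y*cycle_length)``
      -- the per-cycle-equivalent rate compounded once per completed year.
    - ``annual_step``: ``(1+r)**(-y)``.
    - ``per_cycle``: ``(1+r)**(-(t*cycle_length - 1))`` beyond year one (or
      ``(1+r)**(-t*cycle_length)`` when the first year is discounted too).
    """
    if annual_rate < 0:
        raise ParameterError([f"discount rate must be >= 0 (got {annual_rate!r})"])
    if annual_rate == 0:
        return 1.0
    dt = settings.cycle_length_years
    y = int(np.floor(t * dt))
    mode = settings.discounting
    if settings.first_year_undiscounted:
        if y == 0:
            return 1.0
        if mode == "cycle_rate_annual_step":
            return float((1.0 + annual_rate) ** (-y * dt))
        if mode == "annual_step":
            return float((1.0 + annual_rate) ** (-y))
        if mode == "per_cycle":
            return float((1.0 + annual_rate) ** (-(t * dt - 1.0)))
    else:
        if mode == "cycle_rate_annual_step":
            return float((1.0 + annual_rate) ** (-y * dt))
        if mode == "annual_step":
            return float((1.0 + annual_rate) ** (-t * dt))
        if mode == "per_cycle":
            return float((1.0 + annual_rate) ** (-t * dt))
    raise ParameterError([f"unknown discounting mode {mode!r}"])


def _valued_cycles(trace: CohortTrace, settings: ModelSettings) -> list[int]:
    n = trace.n_cycles
    return list(range(0, n + 1)) if settings.include_terminal_cycle else list(range(0, n))


def accumulate_costs(
    trace: CohortTrace,
    costs: CostSet,
    spec: InterventionSpec | None,
    settings: ModelSettings,
    perspective: str = "health_social_care",
    death_trace: CohortTrace | None = None,
) -> float:
    """Discounted cost per cohort member (GBP).

    Care (and, under the societal perspective, informal care) costs accrue on
    each valued occupancy point; the death-event admission cost accrues on the
    flow of new deaths at each death's completion cycle.  ``death_trace``
    optionally supplies the mortality schedule used for death-event costs --
    under the calibrated ``death_cost_schedule='reference'`` convention the
    no-intervention trace is passed here so that end-of-life admission costs
    are common to both arms of a comparison.  The intervention cost, if any,
    is charged once at entry, undiscounted.
    """
    if perspective not in ("health_social_care", "societal"):
        raise ParameterError([f"unknown perspective {perspective!r}"])
    per_cycle_cost = costs.care_vector()
    if perspective == "societal":
        per_cycle_cost = per_cycle_cost + costs.informal_vector()

    rate = settings.discount_rate_costs
    idx = _valued_cycles(trace, settings)
    total = 0.0
    for t in idx:
        total += discount_factor(t, rate, settings) * float(trace.occupancy[t] @ per_cycle_cost)
    if settings.half_cycle_correction:
        for t in (idx[0], idx[-1]):
            total -= 0.5 * discount_factor(t, rate, settings) * float(
                trace.occupancy[t] @ per_cycle_cost
            )
    death_source = death_trace if death_trace is not None else trace
    max_valued = idx[-1]
    for k in range(death_source.n_cycles):
        if k + 1 <= max_valued:
            total += (
                discount_factor(k + 1, rate, settings)
                * float(death_source.new_deaths[k])
                * costs.death_event_cost
            )
    if spec is not None:
        frac = 1.0
        if settings.intervention_cost_alive_only:
            frac = 1.0 - float(trace.occupancy[0, 3])
        total += spec.per_person_cost * frac
    return total


def accumulate_qalys(
    trace: CohortTrace, utilities: UtilitySet, settings: ModelSettings
) -> float:
    """Discounted QALYs per cohort member.

    Each valued occupancy point contributes one cycle length of time lived,
    weighted by the state utility net of the age decrement at that cycle
    (floored at zero).
    """
    u = utilities.utility_vector()
    rate = settings.discount_rate_qalys
    dt = settings.cycle_length_years
    idx = _valued_cycles(trace, settings)

    def cycle_value(t: int) -> float:
        age = settings.entry_age + t * dt
        dec = utilities.decrement(age)
        if dec < 0:
            raise ParameterError([f"decrement schedule returned negative value at age {age}"])
        adj = np.maximum(u - dec, 0.0)
        adj[3] = 0.0  # dead state carries no utility regardless of decrement
        return float(trace.occupancy[t] @ adj) * dt

    total = sum(discount_factor(t, rate, settings) * cycle_value(t) for t in idx)
    if settings.half_cycle_correction:
        for t in (idx[0], idx[-1]):
            total -= 0.5 * discount_factor(t, rate, settings) * cycle_value(t)
    return total


@dataclass(frozen=True)
class PersonLevelResult:
    """Per-person discounted (and undiscounted, for audit) cost and QALYs."""

    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    trace: CohortTrace
    intervention: InterventionSpec | None = None


def run_model(
    params: ModelParameters,
    entry: StateDistribution | None = None,
    intervention: InterventionSpec | None = None,
    perspective: str = "health_social_care",
    death_trace: CohortTrace | None = None,
) -> PersonLevelResult:
    """Run the cohort model once and accumulate per-person cost and QALYs.

    ``entry`` overrides the bundle's entry distribution (used to run the
    post-intervention distribution); ``intervention`` attaches the one-off
    intervention cost.  ``death_trace`` is forwarded to
    :func:`accumulate_costs`.
    """
    validate_parameters(params)
    if entry is None:
        entry = params.entry_distribution
    matrix = build_transition_matrix(params.transitions)
    trace = run_cohort(entry, matrix, params.settings)
    from dataclasses import replace as _replace

    undisc = _replace(
        params.settings, discount_rate_costs=0.0, discount_rate_qalys=0.0
    )
    return PersonLevelResult(
        discounted_cost=accumulate_costs(
            trace, params.costs, intervention, params.settings, perspective, death_trace
        ),
        discounted_qalys=accumulate_qalys(trace, params.utilities, params.settings),
        undiscounted_cost=accumulate_costs(
            trace, params.costs, intervention, undisc, perspective, death_trace
        ),
        undiscounted_qalys=accumulate_qalys(trace, params.utilities, undisc),
        trace=trace,
        intervention=intervention,
    )


def microsimulate(
    params: ModelParameters,
    n_individuals: int,
    rng: np.random.Generator,
    entry: StateDistribution | None = None,
    intervention: InterventionSpec | None = None,
) -> tuple[float, float, float, float]:
    """First-order Monte Carlo oracle for the cohort trace.

    Simulates individuals one transition at a time through the same matrix
    and accounting conventions and returns
    ``(mean cost, mean QALYs, SE cost, SE QALYs)`` per person.  Used to
    validate the deterministic cohort accounting: the cohort-trace values
    must lie within Monte Carlo error of the simulated means.
    """
    validate_parameters(params)
    if entry is None:
        entry = params.entry_distribution
    s = params.settings
    matrix = build_transition_matrix(params.transitions)
    cum = np.cumsum(matrix, axis=1)
    n = s.n_cycles
    dt = s.cycle_length_years

    states = rng.choice(4, size=n_individuals, p=entry.as_array())
    entry_states = states.copy()
    cost = np.zeros(n_individuals)
    qalys = np.zeros(n_individuals)
    care = params.costs.care_vector()
    u = params.utilities.utility_vector()

    df_cost = [discount_factor(t, s.discount_rate_costs, s) for t in range(n + 1)]
    df_q = [discount_factor(t, s.discount_rate_qalys, s) for t in range(n + 1)]
    valued = set(_valued_cycles_n(n, s))

    def add_cycle(t: int, st: np.ndarray):
        age = s.entry_age + t * dt
        dec = params.utilities.decrement(age)
        adj = np.maximum(u - dec, 0.0)
        adj[3] = 0.0
        cost[:] += df_cost[t] * care[st]
        qalys[:] += df_q[t] * adj[st] * dt

    if 0 in valued:
        add_cycle(0, states)
    for k in range(n):
        uni = rng.random(n_individuals)
        alive = states != 3
        new = states.copy()
        new[alive] = (uni[alive, None] > cum[states[alive]]).sum(axis=1)
        died = (states != 3) & (new == 3)
        if (k + 1) <= max(valued):
            cost[died] += df_cost[k + 1] * params.costs.death_event_cost
        states = new
        if (k + 1) in valued:
            add_cycle(k + 1, states)
    if intervention is not None:
        if s.intervention_cost_alive_only:
            cost[entry_states != 3] += intervention.per_person_cost
        else:
            cost += intervention.per_person_cost
    n_sqrt = np.sqrt(n_individuals)
    return (
        float(cost.mean()),
        float(qalys.mean()),
        float(cost.std(ddof=1) / n_sqrt),
        float(qalys.std(ddof=1) / n_sqrt),
    )


def _valued_cycles_n(n: int, settings: ModelSettings) -> list[int]:
    return list(range(0, n + 1)) if settings.include_terminal_cycle else list(range(0, n))


def trace_to_frame(trace: CohortTrace, params: ModelParameters) -> pd.DataFrame:
    """Audit export: per-cycle occupancy, new deaths, discount factors, cycle flows."""
    s = params.settings
    care = params.costs.care_vector()
    u = params.utilities.utility_vector()
    rows = []
    nd = np.concatenate([[0.0], trace.new_deaths])
    for t in range(trace.n_cycles + 1):
        occ = trace.occupancy[t]
        dfc = discount_factor(t, s.discount_rate_costs, s)
        dfq = discount_factor(t, s.discount_rate_qalys, s)
        age = s.entry_age + t * s.cycle_length_years
        dec = params.utilities.decrement(age)
        adj = np.maximum(u - dec, 0.0)
        adj[3] = 0.0
        rows.append(
            {
                "cycle": t,
                **{s_.value: occ[i] for i, s_ in enumerate(STATE_ORDER)},
                "new_deaths": nd[t],
                "discount_factor_costs": dfc,
                "discount_factor_qalys": dfq,
                "cycle_cost": dfc * (float(occ @ care) + nd[t] * params.costs.death_event_cost),
                "cycle_qalys": dfq * float(occ @ adj) * s.cycle_length_years,
            }
        )
    return pd.DataFrame(rows)
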