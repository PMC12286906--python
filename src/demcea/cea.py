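"""Intervention effect operator, incremental analysis, and the scenario suite.

The hypothetical intervention acts only on the entry distribution: a
sample-level effect *e* moves a share of the moderate-dependence occupancy
into low dependence and (unless restricted to the moderate subgroup) the same
share of the high-dependence occupancy into moderate dependence.  Both moves
are computed from the pre-intervention proportions, so the operator is linear
in *e* and additive over donor states.  Downstream cost and QALY accumulation
is linear in the entry distribution, which makes net costs and net QALYs
exactly linear in *e* and the ICER monotone decreasing in *e* for a fixed
intervention cost.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .engine import PersonLevelResult, run_model
from .parameters import (
    InterventionSpec,
    ModelParameters,
    ParameterError,
    StateDistribution,
)

__all__ = [
    "Verdict",
    "Classification",
    "CEAResult",
    "ScenarioGrid",
    "apply_intervention_effect",
    "compare",
    "evaluate_intervention",
    "classify_against_threshold",
    "threshold_effect_search",
    "run_scenario_suite",
]

DEFAULT_WTP = 20_000.0  # GBP per QALY, the national decision threshold in England
UPPER_WTP = 30_000.0


class Verdict(str, enum.Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    ICER = "icer"
    ZERO_QALY_DIFF = "zero_qaly_diff"


class Classification(str, enum.Enum):
    COST_EFFECTIVE = "cost_effective"
    POTENTIALLY = "potentially"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention run against control."""

    cost_per_person: float
    qalys_per_person: float
    control_cost_per_person: float
    control_qalys_per_person: float
    net_cost: float
    net_qalys: float
    verdict: Verdict

    @property
    def icer(self) -> float | None:
        """GBP per QALY, defined only when the verdict is ICER."""
        if self.verdict is Verdict.ICER:
            return self.net_cost / self.net_qalys
        return None

    @property
    def icer_label(self) -> str:
        if self.verdict is Verdict.DOMINANT:
            return "Intervention dominates"
        if self.verdict is Verdict.DOMINATED:
            return "Dominated"
        if self.verdict is Verdict.ZERO_QALY_DIFF:
            return "—"
        return f"£{self.icer:,.0f}"


def apply_intervention_effect(
    entry: StateDistribution, e: float, subgroup_only: bool = False, relative: bool = True
) -> StateDistribution:
    """Redistribute the entry occupancy under a sample-level effect *e*.

    With pre-intervention proportions ``(l, m, h, d)`` and the default
    relative interpretation, the post-intervention distribution is::

        (l + e*m,  m - e*m + e*h,  h - e*h,  d)

    where the ``e*h`` terms vanish when ``subgroup_only`` is set.  Under the
    absolute interpretation (``relative=False``) *e* is a share of the whole
    sample moved out of each donor state, which is infeasible when *e*
    exceeds a donor's occupancy.
    """
    if not (0.0 <= e <= 1.0):
        raise ParameterError([f"effect must be in [0, 1] (got {e!r})"])
    errs = entry.validate()
    if errs:
        raise ParameterError(errs)
    l, m, h, d = entry.low, entry.moderate, entry.high, entry.dead
    if relative:
        move_ml = e * m
        move_hm = 0.0 if subgroup_only else e * h
    else:
        move_ml = e
        move_hm = 0.0 if subgroup_only else e
        if move_ml > m + 1e-12 or move_hm > h + 1e-12:
            raise ParameterError(
                [f"absolute effect {e} exceeds a donor state's occupancy (m={m}, h={h})"]
            )
    out = StateDistribution(
        low=l + move_ml,
        moderate=m - move_ml + move_hm,
        high=h - move_hm,
        dead=d,
    )
    errs = out.validate()
    if errs:
        raise ParameterError(errs)
    return out


def compare(
    intervention_run: PersonLevelResult, control_run: PersonLevelResult
) -> CEAResult:
    """Incremental costs and QALYs (intervention minus control) with verdict."""
    net_cost = intervention_run.discounted_cost - control_run.discounted_cost
    net_qalys = intervention_run.discounted_qalys - control_run.discounted_qalys
    if net_qalys == 0.0:
        verdict = Verdict.ZERO_QALY_DIFF
    elif net_cost < 0 and net_qalys > 0:
        verdict = Verdict.DOMINANT
    elif net_cost > 0 and net_qalys < 0:
        verdict = Verdict.DOMINATED
    else:
        verdict = Verdict.ICER
    return CEAResult(
        cost_per_person=intervention_run.discounted_cost,
        qalys_per_person=intervention_run.discounted_qalys,
        control_cost_per_person=control_run.discounted_cost,
        control_qalys_per_person=control_run.discounted_qalys,
        net_cost=net_cost,
        net_qalys=net_qalys,
        verdict=verdict,
    )


def evaluate_intervention(
    params: ModelParameters,
    intervention: InterventionSpec,
    perspective: str = "health_social_care",
) -> CEAResult:
    """Run the paired cohorts (intervention vs no intervention) and compare.

    The two runs differ only in the entry distribution (and the one-off
    intervention cost).  Under the calibrated
    ``death_cost_schedule='reference'`` convention, the intervention arm's
    death-event costs accrue on the control cohort's mortality schedule so
    that end-of-life admission costs are common to both arms.
    """
    control = run_model(params, perspective=perspective)
    shifted = apply_intervention_effect(
        params.entry_distribution,
        intervention.effect,
        intervention.subgroup_only,
        intervention.relative,
    )
    death_trace = (
        control.trace if params.settings.death_cost_schedule == "reference" else None
    )
    arm = run_model(
        params,
        entry=shifted,
        intervention=intervention,
        perspective=perspective,
        death_trace=death_trace,
    )
    return compare(arm, control)


def classify_against_threshold(
    result: CEAResult, wtp: float = DEFAULT_WTP
) -> Classification:
    """Band a comparison against the willingness-to-pay threshold.

    Dominant results (and ICERs at or below ``wtp``) are cost-effective;
    ICERs between ``wtp`` and £30,000/QALY show potential for
    cost-effectiveness; larger ICERs and dominated results are unlikely to
    be cost-effective.
    """
    if result.verdict is Verdict.ZERO_QALY_DIFF:
        return Classification.UNDEFINED
    if result.verdict is Verdict.DOMINANT:
        return Classification.COST_EFFECTIVE
    if result.verdict is Verdict.DOMINATED:
        return Classification.NOT_COST_EFFECTIVE
    icer = result.icer
    if result.net_qalys < 0:
        # south-west quadrant: saving money while losing QALYs is deemed
        # cost-effective only if savings per QALY forgone exceed the threshold
        return (
            Classification.COST_EFFECTIVE if icer >= wtp else Classification.NOT_COST_EFFECTIVE
        )
    if icer <= wtp:
        return Classification.COST_EFFECTIVE
    if icer <= UPPER_WTP:
        return Classification.POTENTIALLY
    return Classification.NOT_COST_EFFECTIVE


def threshold_effect_search(
    params: ModelParameters,
    intervention_cost: float,
    wtp: float = DEFAULT_WTP,
    grid_step: float | None = None,
    subgroup_only: bool = False,
    tol: float = 1e-4,
    e_max: float = 1.0,
) -> float | None:
    """Smallest sample-level effect that is cost-effective at ``wtp``.

    With ``grid_step`` given, effects ``grid_step, 2*grid_step, ...`` are
    scanned and the smallest cost-effective multiple returned.  Otherwise the
    boundary is located by bisection to ``tol`` absolute tolerance on *e*.
    Returns ``None`` when no effect in ``(0, e_max]`` qualifies.  The search
    asserts that the ICER is monotone non-increasing in *e* over the sampled
    points (it is, by linearity, while net QALYs are positive).
    """

    def is_ce(e: float) -> bool:
        res = evaluate_intervention(
            params,
            InterventionSpec(per_person_cost=intervention_cost, effect=e, subgroup_only=subgroup_only),
        )
        return classify_against_threshold(res, wtp) is Classification.COST_EFFECTIVE

    def icer_at(e: float) -> float:
        res = evaluate_intervention(
            params,
            InterventionSpec(per_person_cost=intervention_cost, effect=e, subgroup_only=subgroup_only),
        )
        return res.icer if res.verdict is Verdict.ICER else -math.inf

    probes = [e_max * f for f in (0.25, 0.5, 0.75, 1.0)]
    icers = [icer_at(e) for e in probes]
    finite = [v for v in icers if math.isfinite(v)]
    assert all(b <= a + 1e-9 for a, b in zip(finite, finite[1:])), (
        "ICER not monotone non-increasing over searched range"
    )

    if grid_step is not None:
        k = 1
        while k * grid_step <= e_max + 1e-12:
            if is_ce(k * grid_step):
                return k * grid_step
            k += 1
        return None

    if not is_ce(e_max):
        return None
    lo, hi = 0.0, e_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid > 0 and is_ce(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class ScenarioGrid:
    """Deterministic sensitivity grid: every listed cell is evaluated."""

    effects: tuple[float, ...] = (0.025, 0.05, 0.075, 0.10)
    horizons_years: tuple[float, ...] = (10.0,)
    intervention_costs: tuple[float, ...] = (570.0,)
    subgroup_only: bool = False
    perspective: str = "health_social_care"
    discount_rates: tuple[tuple[float, float], ...] = ((0.035, 0.035),)
    utility_label: str = "EQ-5D-5L"
    wtp: float = DEFAULT_WTP

    def validate(self) -> list[str]:
        errs = []
        if not self.effects:
            errs.append("scenario grid has no effects")
        if any(e < 0 for e in self.effects):
            errs.append("scenario effects must be >= 0")
        if not self.horizons_years or not self.intervention_costs:
            errs.append("scenario grid has empty horizons or intervention costs")
        return errs


def run_scenario_suite(grid: ScenarioGrid, params: ModelParameters) -> pd.DataFrame:
    """Evaluate every grid cell; one row per (rates, horizon, cost, effect).

    Societal cells are skipped with a warning when informal care costs are
    not configured.  Rows are deterministic and ordered by the loop nesting
    below, so repeated runs produce identical tables.
    """
    errs = grid.validate()
    if errs:
        raise ParameterError(errs)
    if grid.perspective == "societal" and params.costs.informal_care is None:
        warnings.warn(
            "societal perspective requested but informal care costs are not "
            "configured; skipping societal cells",
            stacklevel=2,
        )
        return pd.DataFrame()

    rows = []
    for rc, rq in grid.discount_rates:
        for horizon in grid.horizons_years:
            p = params.replace(
                settings=replace(
                    params.settings,
                    horizon_years=float(horizon),
                    discount_rate_costs=rc,
                    discount_rate_qalys=rq,
                )
            )
            control = run_model(p, perspective=grid.perspective)
            for cost in grid.intervention_costs:
                for e in grid.effects:
                    res = evaluate_intervention(
                        p,
                        InterventionSpec(
                            per_person_cost=cost, effect=e, subgroup_only=grid.subgroup_only
                        ),
                        perspective=grid.perspective,
                    )
                    rows.append(
                        {
                            "discount_rate_costs": rc,
                            "discount_rate_qalys": rq,
                            "horizon_years": horizon,
                            "intervention_cost": cost,
                            "effect": e,
                            "subgroup_only": grid.subgroup_only,
                            "perspective": grid.perspective,
                            "utility_label": grid.utility_label,
                            "control_cost_per_person": control.discounted_cost,
                            "control_qalys_per_person": control.discounted_qalys,
                            "cost_per_person": res.cost_per_person,
                            "qalys_per_person": res.qalys_per_person,
                            "net_cost": res.net_cost,
                            "net_qalys": res.net_qalys,
                            "verdict": res.verdict.value,
                            "icer": res.icer,
                            "classification": classify_against_threshold(res, grid.wtp).value,
                        }
                    )
    return pd.DataFrame(rows)
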