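"""Intervention operator, incremental analysis, threshold logic, scenario suite."""

import numpy as np
import pytest

from demcea import (
    CEAResult,
    InterventionSpec,
    ParameterError,
    ScenarioGrid,
    StateDistribution,
    apply_intervention_effect,
    classify_against_threshold,
    compare,
    evaluate_intervention,
    run_model,
    run_scenario_suite,
    threshold_effect_search,
)
from demcea.cea import Classification, Verdict

ENTRY = StateDistribution(0.60, 0.24, 0.10, 0.06)


def test_effect_operator_zero_is_identity():
    assert apply_intervention_effect(ENTRY, 0.0) == ENTRY


def test_effect_operator_relative_moves_from_pre_intervention_shares():
    out = apply_intervention_effect(ENTRY, 0.025)
    np.testing.assert_allclose(out.as_array(), [0.606, 0.2365, 0.0975, 0.06], atol=1e-15)


def test_effect_operator_subgroup_leaves_high_untouched():
    out = apply_intervention_effect(ENTRY, 0.025, subgroup_only=True)
    np.testing.assert_allclose(out.as_array(), [0.606, 0.234, 0.10, 0.06], atol=1e-15)


def test_effect_operator_absolute_interpretation_and_feasibility():
    out = apply_intervention_effect(ENTRY, 0.025, relative=False)
    np.testing.assert_allclose(out.as_array(), [0.625, 0.24, 0.075, 0.06], atol=1e-15)
    with pytest.raises(ParameterError, match="exceeds"):
        apply_intervention_effect(ENTRY, 0.125, relative=False)


def test_net_outcomes_linear_in_effect(base_params):
    """Net cost and net QALYs scale exactly with e (entry operator is linear)."""
    r1 = evaluate_intervention(base_params, InterventionSpec(per_person_cost=0.0, effect=0.02))
    r2 = evaluate_intervention(base_params, InterventionSpec(per_person_cost=0.0, effect=0.08))
    assert r2.net_cost == pytest.approx(4 * r1.net_cost, abs=1e-9)
    assert r2.net_qalys == pytest.approx(4 * r1.net_qalys, abs=1e-9)


def test_subgroup_additivity_over_donor_states(base_params):
    """Full effect = moderate-subgroup move + high-to-moderate move in isolation."""
    e = 0.04
    full = evaluate_intervention(base_params, InterventionSpec(per_person_cost=0.0, effect=e))
    sub = evaluate_intervention(
        base_params, InterventionSpec(per_person_cost=0.0, effect=e, subgroup_only=True)
    )
    # isolate the high->moderate move via its entry distribution
    base = base_params.entry_distribution
    high_only_entry = StateDistribution(
        base.low, base.moderate + e * base.high, base.high - e * base.high, base.dead
    )
    control = run_model(base_params)
    high_run = run_model(
        base_params,
        entry=high_only_entry,
        death_trace=control.trace,
    )
    high_net_cost = high_run.discounted_cost - control.discounted_cost
    high_net_q = high_run.discounted_qalys - control.discounted_qalys
    assert full.net_cost == pytest.approx(sub.net_cost + high_net_cost, abs=1e-9)
    assert full.net_qalys == pytest.approx(sub.net_qalys + high_net_q, abs=1e-9)


def test_compare_self_is_zero_and_antisymmetric(base_params):
    a = run_model(base_params)
    self_cmp = compare(a, a)
    assert self_cmp.net_cost == 0.0 and self_cmp.net_qalys == 0.0
    assert self_cmp.verdict is Verdict.ZERO_QALY_DIFF
    assert self_cmp.icer is None

    shifted = apply_intervention_effect(base_params.entry_distribution, 0.05)
    b = run_model(base_params, entry=shifted)
    ab, ba = compare(a, b), compare(b, a)
    assert ab.net_cost == pytest.approx(-ba.net_cost, abs=1e-12)
    assert ab.net_qalys == pytest.approx(-ba.net_qalys, abs=1e-12)


def test_verdicts_from_paired_runs(base_params):
    dominant = evaluate_intervention(base_params, InterventionSpec(effect=0.10))
    assert dominant.net_cost < 0 and dominant.net_qalys > 0
    assert dominant.verdict is Verdict.DOMINANT
    assert dominant.icer_label == "Intervention dominates"
    icer = evaluate_intervention(base_params, InterventionSpec(effect=0.025))
    assert icer.verdict is Verdict.ICER
    assert icer.icer > 0


def _result(net_cost, net_qalys, verdict):
    return CEAResult(
        cost_per_person=0.0,
        qalys_per_person=0.0,
        control_cost_per_person=0.0,
        control_qalys_per_person=0.0,
        net_cost=net_cost,
        net_qalys=net_qalys,
        verdict=verdict,
    )


@pytest.mark.parametrize(
    "net_cost,net_qalys,expected",
    [
        (8509 * 0.0125, 0.0125, Classification.COST_EFFECTIVE),
        (22924 * 0.01, 0.01, Classification.POTENTIALLY),
        (31332 * 0.0083, 0.0083, Classification.NOT_COST_EFFECTIVE),
    ],
)
def test_threshold_bands(net_cost, net_qalys, expected):
    res = _result(net_cost, net_qalys, Verdict.ICER)
    assert classify_against_threshold(res) is expected


def test_threshold_special_verdicts():
    assert classify_against_threshold(_result(-1.0, 1.0, Verdict.DOMINANT)) is Classification.COST_EFFECTIVE
    assert classify_against_threshold(_result(1.0, -1.0, Verdict.DOMINATED)) is Classification.NOT_COST_EFFECTIVE
    assert classify_against_threshold(_result(0.0, 0.0, Verdict.ZERO_QALY_DIFF)) is Classification.UNDEFINED


def test_icer_monotone_non_increasing_in_effect(base_params):
    icers = [
        evaluate_intervention(base_params, InterventionSpec(effect=e)).icer
        for e in (0.025, 0.05, 0.075)
    ]
    assert icers[0] > icers[1] > icers[2]


def test_threshold_search_on_published_grid(base_params):
    """On the 2.5% grid at £570 the smallest cost-effective effect is 7.5%."""
    e = threshold_effect_search(base_params, 570.0, grid_step=0.025, e_max=0.10)
    assert e == pytest.approx(0.075)


def test_threshold_search_infinite_wtp_returns_first_grid_point(base_params):
    e = threshold_effect_search(base_params, 570.0, wtp=1e12, grid_step=0.025, e_max=0.10)
    assert e == pytest.approx(0.025)


def test_threshold_search_continuous_hits_the_wtp_boundary(base_params):
    e_star = threshold_effect_search(base_params, 1000.0, tol=1e-6, e_max=0.5)
    res = evaluate_intervention(base_params, InterventionSpec(per_person_cost=1000.0, effect=e_star))
    assert res.icer == pytest.approx(20_000, rel=1e-3)
    # on the coarse published grid the same question answers 12.5%
    assert threshold_effect_search(base_params, 1000.0, grid_step=0.025, e_max=0.5) == pytest.approx(0.125)


def test_threshold_search_unreachable(base_params):
    assert threshold_effect_search(base_params, 1e9, e_max=0.5) is None


def test_scenario_suite_shape_and_determinism(base_params):
    grid = ScenarioGrid(effects=(0.025, 0.05, 0.075, 0.10), horizons_years=(10.0, 5.0))
    df1 = run_scenario_suite(grid, base_params)
    df2 = run_scenario_suite(grid, base_params)
    assert len(df1) == 8
    assert df1.equals(df2)
    assert set(df1["verdict"]) <= {"dominant", "icer"}


def test_scenario_suite_empty_effects_errors(base_params):
    with pytest.raises(ParameterError, match="no effects"):
        run_scenario_suite(ScenarioGrid(effects=()), base_params)


def test_scenario_suite_societal_without_informal_costs_skips(base_params):
    with pytest.warns(UserWarning, match="informal"):
        df = run_scenario_suite(ScenarioGrid(perspective="societal"), base_params)
    assert df.empty
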