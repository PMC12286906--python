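"""Cohort engine: matrix construction, trace propagation, discounting, accounting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from demcea import (
    InterventionSpec,
    ModelSettings,
    ParameterError,
    StateDistribution,
    TransitionModel,
    accumulate_costs,
    accumulate_qalys,
    build_transition_matrix,
    discount_factor,
    microsimulate,
    run_cohort,
    run_model,
)
from demcea.engine import CohortTrace, trace_to_frame

BASE_TM = TransitionModel(0.15, 0.07, 0.02, 0.038, 0.05)


def test_transition_matrix_rows_from_base_parameters():
    m = build_transition_matrix(BASE_TM)
    np.testing.assert_allclose(m[0], [0.83, 0.15, 0.0, 0.02], atol=1e-15)
    np.testing.assert_allclose(m[1], [0.0, 0.892, 0.07, 0.038], atol=1e-15)
    np.testing.assert_allclose(m[2], [0.0, 0.0, 0.95, 0.05], atol=1e-15)
    np.testing.assert_allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=0)


def test_transition_matrix_structural_zeros_and_identity():
    m = build_transition_matrix(BASE_TM)
    assert m[0, 2] == 0.0  # no low->high jump within one cycle
    assert np.tril(m, -1).sum() == 0.0  # no backward moves
    identity = build_transition_matrix(TransitionModel(0, 0, 0, 0, 0))
    np.testing.assert_array_equal(identity, np.eye(4))


def test_incompatible_probabilities_rejected():
    with pytest.raises(ParameterError, match="exceeds 1"):
        build_transition_matrix(TransitionModel(0.99, 0.07, 0.02, 0.038, 0.05))


def test_cohort_trace_hand_computed_products():
    settings = ModelSettings(horizon_years=0.5)  # 2 cycles
    trace = run_cohort(StateDistribution(1, 0, 0, 0), build_transition_matrix(BASE_TM), settings)
    np.testing.assert_allclose(trace.occupancy[1], [0.83, 0.15, 0.0, 0.02], atol=1e-15)
    assert trace.occupancy[2, 0] == pytest.approx(0.83**2, abs=1e-15)


def test_dead_entry_cohort_stays_dead():
    settings = ModelSettings(horizon_years=10)
    trace = run_cohort(StateDistribution(0, 0, 0, 1), build_transition_matrix(BASE_TM), settings)
    np.testing.assert_array_equal(trace.occupancy, np.tile([0, 0, 0, 1.0], (41, 1)))
    assert trace.new_deaths.sum() == 0.0


@st.composite
def transition_models(draw):
    p_lm = draw(st.floats(0, 0.5))
    p_mh = draw(st.floats(0, 0.5))
    p_dl = draw(st.floats(0, 0.5))
    p_dm = draw(st.floats(0, 0.5))
    p_dh = draw(st.floats(0, 1))
    return TransitionModel(p_lm, p_mh, p_dl, p_dm, p_dh)


@st.composite
def entry_distributions(draw):
    raw = np.array([draw(st.floats(0.01, 1)) for _ in range(4)])
    return StateDistribution.from_array(raw / raw.sum())


@given(transition_models(), entry_distributions())
def test_trace_conservation_and_monotonicity(tm, entry):
    """Occupancy is conserved; dead share never falls, low share never rises."""
    trace = run_cohort(entry, build_transition_matrix(tm), ModelSettings(horizon_years=5))
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
    assert (trace.occupancy >= -1e-15).all()
    assert (np.diff(trace.dead) >= -1e-15).all()
    assert (np.diff(trace.occupancy[:, 0]) <= 1e-15).all()
    assert (trace.new_deaths >= -1e-15).all()
    np.testing.assert_allclose(trace.new_deaths, np.diff(trace.dead), atol=1e-15)


def test_discount_factor_conventions():
    s = ModelSettings()  # calibrated default mode
    assert discount_factor(3, 0.035, s) == 1.0  # within the first year
    assert discount_factor(10, 0.0, s) == 1.0  # zero rate never discounts
    assert discount_factor(4, 0.035, s) == pytest.approx(1.035 ** (-0.25), abs=1e-12)
    textbook = dataclasses.replace(s, discounting="annual_step")
    assert discount_factor(4, 0.035, textbook) == pytest.approx(1 / 1.035, abs=1e-12)
    assert discount_factor(39, 0.035, textbook) == pytest.approx(1.035 ** (-9), abs=1e-12)
    with pytest.raises(ParameterError):
        discount_factor(4, -0.01, s)


def test_first_year_flag_changes_year_zero_only_in_default_mode():
    s = ModelSettings()
    s_off = dataclasses.replace(s, first_year_undiscounted=False)
    for t in range(41):
        f_on, f_off = discount_factor(t, 0.035, s), discount_factor(t, 0.035, s_off)
        assert f_on == f_off  # year-0 factor is 1 under the annual-step exponent anyway


def test_costs_dead_cohort_accrues_nothing(base_params):
    trace = run_cohort(
        StateDistribution(0, 0, 0, 1),
        build_transition_matrix(base_params.transitions),
        base_params.settings,
    )
    assert accumulate_costs(trace, base_params.costs, None, base_params.settings) == 0.0
    assert accumulate_qalys(trace, base_params.utilities, base_params.settings) == 0.0


def test_single_cycle_entry_only_accounting(base_params):
    """Valuing only the entry point: one cycle of high-dependence care, no death cost."""
    s = dataclasses.replace(
        base_params.settings,
        horizon_years=0.25,
        include_terminal_cycle=False,
        discount_rate_costs=0.0,
        discount_rate_qalys=0.0,
    )
    trace = run_cohort(
        StateDistribution(0, 0, 1, 0), build_transition_matrix(base_params.transitions), s
    )
    assert accumulate_costs(trace, base_params.costs, None, s) == pytest.approx(8510.0)
    trace_low = run_cohort(
        StateDistribution(1, 0, 0, 0), build_transition_matrix(base_params.transitions), s
    )
    assert accumulate_qalys(trace_low, base_params.utilities, s) == pytest.approx(0.788 * 0.25)


def test_discounted_never_exceeds_undiscounted(base_params):
    res = run_model(base_params)
    assert res.discounted_cost <= res.undiscounted_cost
    assert res.discounted_qalys <= res.undiscounted_qalys
    max_u = max(v for k, v in base_params.utilities.values.items() if k.is_alive)
    assert res.discounted_qalys <= base_params.settings.horizon_years * max_u * 1.03


def test_intervention_cost_charged_undiscounted_at_entry(base_params):
    with_iv = run_model(base_params, intervention=InterventionSpec(per_person_cost=570.0))
    without = run_model(base_params)
    assert with_iv.discounted_cost - without.discounted_cost == pytest.approx(570.0)
    alive_only = base_params.replace(
        settings=dataclasses.replace(base_params.settings, intervention_cost_alive_only=True)
    )
    with_iv2 = run_model(alive_only, intervention=InterventionSpec(per_person_cost=570.0))
    assert with_iv2.discounted_cost - without.discounted_cost == pytest.approx(570.0 * 0.94)


def test_microsimulation_oracle_agrees_with_cohort_trace(base_params):
    """First-order Monte Carlo at 30k individuals brackets the deterministic values."""
    rng = np.random.default_rng(12345)
    mc_cost, mc_q, se_cost, se_q = microsimulate(base_params, 30_000, rng)
    det = run_model(base_params)
    assert abs(mc_cost - det.discounted_cost) < 3 * se_cost
    assert abs(mc_q - det.discounted_qalys) < 3 * se_q


def test_decrement_insensitivity_of_increments(base_params):
    """A state-independent additive decrement barely moves incremental results."""
    from demcea import apply_intervention_effect

    shifted = apply_intervention_effect(base_params.entry_distribution, 0.05)
    dec_params = base_params.replace(
        utilities=dataclasses.replace(
            base_params.utilities, decrement_schedule={0.0: 0.05}
        )
    )
    ones = dataclasses.replace(
        base_params.utilities,
        values={k: (1.0 if k.is_alive else 0.0) for k in base_params.utilities.values},
        decrement_schedule={},
    )

    def nets(p):
        a = run_model(p, entry=shifted)
        b = run_model(p)
        return a.discounted_cost - b.discounted_cost, a.discounted_qalys - b.discounted_qalys

    dc0, dq0 = nets(base_params)
    dc1, dq1 = nets(dec_params)
    assert dc1 == pytest.approx(dc0, abs=1e-9)  # costs don't see utilities
    # discounted life-year difference bounds the decrement effect on net QALYs
    ly_params = base_params.replace(utilities=ones)
    dly = nets(ly_params)[1]
    assert abs(dq1 - dq0) < 0.05 * abs(dly) + 1e-12


def test_trace_export_contains_audit_columns(base_params):
    res = run_model(base_params)
    df = trace_to_frame(res.trace, base_params)
    assert len(df) == 41
    for col in ("cycle", "low", "dead", "new_deaths", "discount_factor_costs", "cycle_cost"):
        assert col in df.columns
    assert df["new_deaths"].iloc[0] == 0.0
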