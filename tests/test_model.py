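"""Stock-flow engine: flow arithmetic, conservation, closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physupply.model import (
    MissingParameterError,
    ModelError,
    ParameterTable,
    Scenario,
    StockState,
    backcast,
    simulate,
    step,
)

from conftest import make_parameter_table, make_single_region_scenario


def test_zero_rates_identity_step():
    """With every rate and quota at zero, a step only advances the year."""
    scen = make_single_region_scenario(initial_physicians=500.0)
    before = scen.initial_state.copy()
    after = step(scen.initial_state, scen.parameters)
    assert after.year == before.year + 1
    assert (after.physicians == before.physicians).all()
    assert (after.students == before.students).all()
    assert (after.residents == before.residents).all()
    assert after.physicians_external == before.physicians_external
    assert after.cumulative_exits == before.cumulative_exits


def test_retirement_only_single_flow():
    """One region, retirement r, no intake: s -> s(1-r)."""
    scen = make_single_region_scenario(
        initial_physicians=1000.0, retirement_rate=0.05
    )
    after = step(scen.initial_state, scen.parameters)
    assert after.physicians["A"] == pytest.approx(950.0)
    assert after.cumulative_exits == pytest.approx(50.0)


def _flow_ledger(state, params):
    """Independent flow ledger: re-derive every within-year flow from
    the career-path description (no grad-school return) and return the
    implied intake and total exits."""
    row = params.at(state.year)
    grads = state.students[-1]
    passers = grads * row["pass_rate"]
    exam_fail = grads.sum() - passers.sum()
    to_grad = passers * row["grad_school_rate"]
    nonclin = (passers - to_grad) * row["nonclinical_rate"]
    to_match = passers - to_grad - nonclin
    unmatched = to_match.sum() * (1 - row["match_rate"])
    completers = state.residents[-1]
    staying = completers * np.array(
        [row["stay_rate_general"], row["stay_rate_regional"]]
    )
    leaving = completers.sum() - staying.sum()
    external = state.physicians_external + unmatched + leaving
    inflow = row["inflow_rate"] * external
    pool = state.physicians.sum() + staying.sum() + inflow
    pool -= row["outflow_rate"] * pool
    removal = (row["retirement_rate"] + row["other_rates"]) * pool
    intake = row["general_quota"] + row["regional_quota"]
    exits = exam_fail + to_grad.sum() + nonclin.sum() + removal
    return float(intake), float(exits)


def test_conservation_against_flow_ledger(scenario):
    """Delta(total incl. external and exits) == intake, and the booked
    exits match a ledger that records every exit flow independently."""
    state = scenario.initial_state.copy()
    for _ in range(15):
        intake, exits = _flow_ledger(state, scenario.parameters)
        after = step(state, scenario.parameters)
        assert after.total() - state.total() == pytest.approx(intake, abs=1e-6)
        assert after.cumulative_exits - state.cumulative_exits == pytest.approx(
            exits, abs=1e-6
        )
        state = after


def test_simulate_horizon_equals_baseline():
    scen = make_single_region_scenario(horizon=2000)
    traj = simulate(scen)
    assert len(traj.states) == 1
    assert traj.states[0].physicians.equals(scen.initial_state.physicians)


def test_geometric_decay_closed_form():
    """Retirement-only stock follows P0 (1-r)^t exactly."""
    r, p0 = 0.04, 12019.0
    scen = make_single_region_scenario(
        initial_physicians=p0, retirement_rate=r, horizon=2030
    )
    traj = simulate(scen)
    for t, state in enumerate(traj.states):
        assert state.physicians["A"] == pytest.approx(
            p0 * (1 - r) ** t, abs=1e-9 * p0
        )


def test_constant_entry_converges_to_fixed_point():
    """Constant absolute entry a with retirement r converges
    monotonically to the fixed point of P' = (P + a)(1 - r)."""
    a, r = 400.0, 0.05
    inflow = pd.Series(a, index=range(2000, 2101))
    params = make_parameter_table(retirement_rate=r, years=range(2000, 2102))
    scen = make_single_region_scenario(
        initial_physicians=100.0, horizon=2100, params=params
    )
    scen.absolute_inflow = inflow
    scen.initial_state.physicians_external = 1e9  # never binding
    traj = simulate(scen)
    series = [s.physicians["A"] for s in traj.states]
    fixed_point = a * (1 - r) / r
    diffs = np.diff(series)
    assert (diffs > 0).all()
    gaps = fixed_point - np.asarray(series)
    assert (gaps > 0).all() and (np.diff(gaps) < 0).all()
    assert series[-1] == pytest.approx(fixed_point, rel=1e-2)


def test_regional_quota_monotonicity(profile, params, scenario):
    """Raising the regional quota never lowers any prefecture total."""
    base = simulate(scenario).total_prefecture()
    rates = params.rates.copy()
    rates["regional_quota"] = rates["regional_quota"] + 20.0
    bigger_params = ParameterTable(
        rates=rates, smsa_option_rates=params.smsa_option_rates
    )
    scen2 = Scenario(
        baseline_year=scenario.baseline_year,
        horizon_year=scenario.horizon_year,
        report_years=scenario.report_years,
        initial_state=scenario.initial_state.copy(),
        parameters=bigger_params,
    )
    boosted = simulate(scen2).total_prefecture()
    assert (boosted >= base - 1e-9).all()


def test_linearity_in_headcounts(scenario, params):
    """Doubling initial stocks and quota intakes doubles every stock."""
    base = simulate(scenario)
    rates = params.rates.copy()
    for c in ("general_quota", "regional_quota"):
        rates[c] = rates[c] * 2
    doubled_params = ParameterTable(
        rates=rates, smsa_option_rates=params.smsa_option_rates
    )
    s0 = scenario.initial_state
    doubled_state = StockState(
        year=s0.year,
        students=s0.students * 2,
        residents=s0.residents * 2,
        physicians=s0.physicians * 2,
        physicians_external=s0.physicians_external * 2,
        cumulative_exits=s0.cumulative_exits * 2,
    )
    scen2 = Scenario(
        baseline_year=scenario.baseline_year,
        horizon_year=scenario.horizon_year,
        report_years=scenario.report_years,
        initial_state=doubled_state,
        parameters=doubled_params,
    )
    doubled = simulate(scen2)
    for s_base, s_doubled in zip(base.states, doubled.states):
        np.testing.assert_allclose(
            s_doubled.physicians, 2 * s_base.physicians, rtol=1e-12
        )
        np.testing.assert_allclose(
            s_doubled.students, 2 * s_base.students, rtol=1e-12
        )


def test_determinism_bit_identical(scenario):
    a, b = simulate(scenario), simulate(scenario)
    for sa, sb in zip(a.states, b.states):
        assert (sa.physicians == sb.physicians).all()
        assert (sa.students == sb.students).all()
        assert (sa.residents == sb.residents).all()
        assert sa.physicians_external == sb.physicians_external
        assert sa.cumulative_exits == sb.cumulative_exits


def test_backcast_is_simulate_on_window(profile, params):
    from physupply.synthetic import historic_scenario

    scen = historic_scenario(profile, params, 1998, 2008)
    via_backcast = backcast(scen, 1998, 2008)
    via_simulate = simulate(scen)
    pd.testing.assert_series_equal(
        via_backcast.annual_totals(), via_simulate.annual_totals()
    )


def test_backcast_zero_rate_window_is_constant():
    scen = make_single_region_scenario(
        baseline=1998, horizon=2008, years=range(1995, 2041)
    )
    traj = backcast(scen, 1998, 2008)
    totals = traj.annual_totals()
    assert (totals == totals.iloc[0]).all()


def test_missing_parameter_year_is_explicit():
    params = make_parameter_table(years=range(2005, 2041))
    scen = make_single_region_scenario(params=params)
    with pytest.raises(MissingParameterError, match="2000"):
        step(scen.initial_state, params)


def test_piecewise_constant_extension_is_logged(caplog):
    params = make_parameter_table(years=range(2000, 2005),
                                  retirement_rate=0.02)
    with caplog.at_level("WARNING"):
        row = params.at(2010)
    assert row["retirement_rate"] == 0.02
    assert "piecewise-constant" in caplog.text


def test_prefecture_total_equals_region_sum(trajectory):
    by_region = trajectory.totals_by_region().sum(axis=1)
    pd.testing.assert_series_equal(
        trajectory.total_prefecture(), by_region,
        check_names=False, atol=1e-6,
    )


@pytest.mark.parametrize(
    "bad",
    [
        {"pass_rate": 1.5},
        {"retirement_rate": -0.1},
        {"general_quota": -10.0},
    ],
)
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ModelError):
        make_parameter_table(**bad)


def test_option_rates_must_sum_to_one():
    rates = make_parameter_table().rates
    with pytest.raises(ModelError, match="sum to 1"):
        ParameterTable(
            rates=rates, smsa_option_rates=pd.Series({"A": 0.6, "B": 0.5})
        )


def test_excessive_removal_rate_raises():
    scen = make_single_region_scenario(
        retirement_rate=0.7, other_rates=0.6
    )
    with pytest.raises(ModelError, match="negative"):
        step(scen.initial_state, scen.parameters)


def test_grad_school_return_recovers_headcount():
    """With the return flag on, graduate-school entrants re-enter the
    practising pool after the delay instead of exiting."""
    params = make_parameter_table(
        pass_rate=1.0, match_rate=1.0, grad_school_rate=0.5,
        stay_rate_general=1.0, stay_rate_regional=1.0,
    )
    base = make_single_region_scenario(initial_physicians=0.0, params=params,
                                       horizon=2020)
    base.initial_state.students[:] = [[100.0, 0.0]] * 6
    with_return = make_single_region_scenario(
        initial_physicians=0.0, params=params, horizon=2020
    )
    with_return.initial_state.students[:] = [[100.0, 0.0]] * 6
    with_return.grad_school_return = True
    t_no = simulate(base).state_at(2020)
    t_yes = simulate(with_return).state_at(2020)
    assert t_yes.physicians["A"] > t_no.physicians["A"]
    assert t_yes.total() == pytest.approx(t_no.total())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    pass_rate=st.floats(0, 1),
    match_rate=st.floats(0, 1),
    stay=st.floats(0, 1),
    retirement=st.floats(0, 0.5),
    other=st.floats(0, 0.5),
    quota=st.floats(0, 500),
)
def test_nonnegativity_and_ledger_property(
    pass_rate, match_rate, stay, retirement, other, quota
):
    """For any rates in range, stocks stay non-negative and the ledger
    closes at every step."""
    scen = make_single_region_scenario(
        initial_physicians=5000.0,
        horizon=2015,
        pass_rate=pass_rate,
        match_rate=match_rate,
        stay_rate_general=stay,
        stay_rate_regional=stay,
        retirement_rate=retirement,
        other_rates=other,
        general_quota=quota,
        inflow_rate=0.01,
        outflow_rate=0.02,
    )
    scen.initial_state.students[:] = [[50.0, 10.0]] * 6
    scen.initial_state.physicians_external = 1000.0
    traj = simulate(scen)
    for prev, cur in zip(traj.states, traj.states[1:]):
        assert (cur.physicians >= 0).all()
        assert (cur.students >= 0).all() and (cur.residents >= 0).all()
        assert cur.physicians_external >= 0 and cur.cumulative_exits >= 0
        assert cur.total() - prev.total() == pytest.approx(quota, abs=1e-6)
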