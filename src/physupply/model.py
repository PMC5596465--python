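"""Discrete-time stock-flow engine for regional physician supply.

The model tracks annual cohorts along the Japanese physician career
path: two medical-school admission streams (a general quota and a
scholarship-bound regional quota), the national licensing examination,
residency matching, and entry into per-region (SMSA) practising pools.
A single external pool aggregates physicians outside the study
prefecture; retirement, non-clinical career choices and other attrition
are booked to a cumulative exits counter so the headcount ledger closes
exactly: at every step the change in total headcount (all stocks plus
external plus exits) equals the quota intake.

Everything is deterministic and linear in headcounts — stocks are
real-valued expected counts, rounded only at report time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: quota-stream axis order used by every (cohort-year x quota) array
GENERAL, REGIONAL = 0, 1
QUOTA_NAMES = ("general", "regional")

RATE_COLUMNS = (
    "pass_rate",
    "match_rate",
    "grad_school_rate",
    "nonclinical_rate",
    "stay_rate_general",
    "stay_rate_regional",
    "other_pref_rate",
    "inflow_rate",
    "outflow_rate",
    "retirement_rate",
    "other_rates",
)
QUOTA_COLUMNS = ("general_quota", "regional_quota")
PARAMETER_COLUMNS = QUOTA_COLUMNS + RATE_COLUMNS


class ModelError(ValueError):
    """Inconsistent state or parameters detected by the engine."""


class MissingParameterError(ModelError):
    """A simulated year falls before the first defined parameter year."""


@dataclass
class ParameterTable:
    """Career-path rates and quota intakes by calendar year.

    Parameters
    ----------
    rates
        DataFrame indexed by calendar year with one column per entry of
        :data:`PARAMETER_COLUMNS`.  Quotas are non-negative entrant
        counts; every rate lies in [0, 1].
    smsa_option_rates
        Series indexed by region id giving the fraction of new
        in-prefecture physicians who choose each sub-region as their
        place of practice; must sum to 1.

    Years beyond the last defined row are extended piecewise-constant
    (logged); years before the first row raise
    :class:`MissingParameterError`.
    """

    rates: pd.DataFrame
    smsa_option_rates: pd.Series

    def __post_init__(self) -> None:
        missing = [c for c in PARAMETER_COLUMNS if c not in self.rates.columns]
        if missing:
            raise ModelError(f"parameter table missing columns: {missing}")
        self.rates = self.rates.sort_index()
        r = self.rates[list(RATE_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(r).all() or (r < 0).any() or (r > 1).any():
            raise ModelError("every rate must be a finite fraction in [0, 1]")
        q = self.rates[list(QUOTA_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(q).all() or (q < 0).any():
            raise ModelError("quota intakes must be finite and non-negative")
        opt = self.smsa_option_rates.astype(float)
        if (opt < 0).any():
            raise ModelError("smsa_option_rates must be non-negative")
        if abs(opt.sum() - 1.0) > 1e-9:
            raise ModelError(
                f"smsa_option_rates must sum to 1 (got {opt.sum():.12f})"
            )
        self.smsa_option_rates = opt

    @property
    def regions(self) -> list[str]:
        return list(self.smsa_option_rates.index)

    def at(self, year: int) -> pd.Series:
        """Parameter row for ``year`` with piecewise-constant extension."""
        idx = self.rates.index
        if year < idx[0]:
            raise MissingParameterError(
                f"no parameters defined for year {year} "
                f"(table starts at {idx[0]})"
            )
        if year in idx:
            return self.rates.loc[year]
        source = idx[idx.searchsorted(year, side="right") - 1]
        logger.warning(
            "parameters for year %d not defined; extending year %d "
            "piecewise-constant", year, source,
        )
        return self.rates.loc[source]


@dataclass
class StockState:
    """Headcounts of every cohort at the start of one calendar year.

    ``students`` and ``residents`` are (program-year x quota-stream)
    arrays with row 0 the newest cohort; ``grad_school`` holds the
    optional delayed graduate-school pipeline.  ``physicians`` is a
    Series of practising headcounts per sub-region.
    """

    year: int
    students: np.ndarray
    residents: np.ndarray
    physicians: pd.Series
    physicians_external: float = 0.0
    cumulative_exits: float = 0.0
    grad_school: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.students = np.asarray(self.students, dtype=float)
        self.residents = np.asarray(self.residents, dtype=float)
        self.physicians = self.physicians.astype(float)
        if self.grad_school is not None:
            self.grad_school = np.asarray(self.grad_school, dtype=float)
        self.validate()

    def validate(self) -> None:
        pools = [self.students, self.residents, self.physicians.to_numpy(),
                 np.asarray([self.physicians_external, self.cumulative_exits])]
        if self.grad_school is not None:
            pools.append(self.grad_school)
        for a in pools:
            if not np.isfinite(a).all():
                raise ModelError(f"non-finite headcount in state {self.year}")
            if (a < -1e-9).any():
                raise ModelError(f"negative headcount in state {self.year}")

    @property
    def regions(self) -> list[str]:
        return list(self.physicians.index)

    def total(self) -> float:
        """Grand total across every stock, the external pool and exits."""
        t = (self.students.sum() + self.residents.sum()
             + float(self.physicians.sum())
             + self.physicians_external + self.cumulative_exits)
        if self.grad_school is not None:
            t += self.grad_school.sum()
        return float(t)

    def copy(self) -> "StockState":
        return StockState(
            year=self.year,
            students=self.students.copy(),
            residents=self.residents.copy(),
            physicians=self.physicians.copy(),
            physicians_external=self.physicians_external,
            cumulative_exits=self.cumulative_exits,
            grad_school=None if self.grad_school is None
            else self.grad_school.copy(),
        )


@dataclass
class Scenario:
    """A complete, runnable simulation configuration."""

    baseline_year: int
    horizon_year: int
    initial_state: StockState
    parameters: ParameterTable
    report_years: list[int] | None = None
    school_duration: int = 6
    residency_duration: int = 2
    #: graduate-school entrants re-enter clinical practice after this
    #: many years when ``grad_school_return`` is on; otherwise they exit.
    grad_school_return: bool = False
    grad_school_delay: int = 4
    #: optional exogenous absolute inflow (headcount/year, indexed by
    #: year); overrides rate-based inflow from the external pool.
    absolute_inflow: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.report_years is None:
            self.report_years = list(
                range(self.baseline_year, self.horizon_year + 1, 5)
            )
        self.report_years = sorted(int(y) for y in self.report_years)
        if self.baseline_year > self.horizon_year:
            raise ModelError("baseline_year must not exceed horizon_year")
        if (self.report_years[0] < self.baseline_year
                or self.report_years[-1] > self.horizon_year):
            raise ModelError("report_years must lie within "
                             "[baseline_year, horizon_year]")
        if self.initial_state.year != self.baseline_year:
            raise ModelError(
                f"initial_state.year ({self.initial_state.year}) must equal "
                f"baseline_year ({self.baseline_year})"
            )
        if self.initial_state.students.shape != (self.school_duration, 2):
            raise ModelError("students array must be (school_duration, 2)")
        if self.initial_state.residents.shape != (self.residency_duration, 2):
            raise ModelError("residents array must be (residency_duration, 2)")
        if list(self.initial_state.physicians.index) != list(
                self.parameters.smsa_option_rates.index):
            raise ModelError("state regions and smsa_option_rates regions "
                             "must match")


@dataclass
class Trajectory:
    """Annual state snapshots plus report-year aggregates."""

    states: list[StockState]
    report_years: list[int]

    def state_at(self, year: int) -> StockState:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not simulated")

    @property
    def regions(self) -> list[str]:
        return self.states[0].regions

    def totals_by_region(self) -> pd.DataFrame:
        """Per-region practising headcount at each report year."""
        rows = {y: self.state_at(y).physicians for y in self.report_years}
        return pd.DataFrame(rows).T.rename_axis(index="year")

    def total_prefecture(self) -> pd.Series:
        totals = self.totals_by_region().sum(axis=1)
        totals.name = "physicians"
        return totals

    def annual_totals(self) -> pd.Series:
        """Prefecture practising headcount for every simulated year."""
        # np.sum over the raw array keeps the reduction order identical
        # to per-region tables summed the same way (exact round trips)
        return pd.Series(
            {s.year: float(np.sum(s.physicians.to_numpy()))
             for s in self.states},
            name="physicians",
        ).rename_axis("year")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format stock table: year, region_id, stock_name, headcount."""
        records = []
        for s in self.states:
            for i in range(s.students.shape[0]):
                for q, qname in enumerate(QUOTA_NAMES):
                    records.append((s.year, "", f"students_y{i + 1}_{qname}",
                                    s.students[i, q]))
            for i in range(s.residents.shape[0]):
                for q, qname in enumerate(QUOTA_NAMES):
                    records.append((s.year, "", f"residents_y{i + 1}_{qname}",
                                    s.residents[i, q]))
            for region, count in s.physicians.items():
                records.append((s.year, region, "physicians", count))
            records.append((s.year, "", "physicians_external",
                            s.physicians_external))
            records.append((s.year, "", "cumulative_exits",
                            s.cumulative_exits))
        return pd.DataFrame(
            records, columns=["year", "region_id", "stock_name", "headcount"]
        )


def step(
    state: StockState,
    params: ParameterTable,
    *,
    grad_school_return: bool = False,
    grad_school_delay: int = 4,
    absolute_inflow: pd.Series | None = None,
) -> StockState:
    """Advance the career-path model by one year.

    Flow order within the year: quota intake enters first-year medicine;
    cohorts advance; final-year students sit the licensing exam
    (failures exit); passers branch to graduate school and non-clinical
    careers before residency matching (unmatched passers move to the
    external pool); residency completers split by quota-specific stay
    rate between the prefecture (allocated across sub-regions by the
    SMSA option rates) and the external pool; rate-based inflow from the
    external pool and outflow to it are exchanged; retirement and other
    attrition remove headcount from each region into cumulative exits.
    """
    try:
        row = params.at(state.year)
    except MissingParameterError as exc:
        raise MissingParameterError(f"step at year {state.year}: {exc}") from exc

    s = state.copy()
    regions = params.smsa_option_rates

    # Medical school: intake enters year 1, cohorts advance, final year sits
    # the national exam.
    graduating = s.students[-1].copy()
    s.students[1:] = s.students[:-1]
    s.students[0] = (row["general_quota"], row["regional_quota"])

    passers = graduating * row["pass_rate"]
    s.cumulative_exits += float((graduating - passers).sum())  # exam failures

    # Pre-matching branches: graduate school, then non-clinical careers.
    to_grad = passers * row["grad_school_rate"]
    passers = passers - to_grad
    nonclinical = passers * row["nonclinical_rate"]
    s.cumulative_exits += float(nonclinical.sum())
    passers = passers - nonclinical

    matched = passers * row["match_rate"]
    s.physicians_external += float((passers - matched).sum())

    # Residency: completers leave, matched passers enter year 1.
    completers = s.residents[-1].copy()
    s.residents[1:] = s.residents[:-1]
    s.residents[0] = matched

    # Graduate-school pipeline (optional return to clinical practice).
    if grad_school_return:
        if s.grad_school is None:
            s.grad_school = np.zeros((grad_school_delay, 2))
        completers = completers + s.grad_school[-1]
        s.grad_school[1:] = s.grad_school[:-1]
        s.grad_school[0] = to_grad
    else:
        s.cumulative_exits += float(to_grad.sum())

    # Completers choose the prefecture (stay) or elsewhere, by quota stream.
    stay_rates = np.array(
        [row["stay_rate_general"], row["stay_rate_regional"]]
    )
    staying = completers * stay_rates
    s.physicians_external += float((completers - staying).sum())
    s.physicians = s.physicians + float(staying.sum()) * regions

    # Inflow from / outflow to the external physician pool.
    if absolute_inflow is not None and state.year in absolute_inflow.index:
        inflow = float(absolute_inflow.loc[state.year])
        inflow = min(inflow, s.physicians_external)
    else:
        inflow = row["inflow_rate"] * s.physicians_external
    s.physicians_external -= inflow
    s.physicians = s.physicians + inflow * regions

    outflow = row["outflow_rate"] * s.physicians
    s.physicians = s.physicians - outflow
    s.physicians_external += float(outflow.sum())

    # Retirement plus other attrition (mortality, drop-out, emigration).
    removal_rate = row["retirement_rate"] + row["other_rates"]
    if removal_rate > 1.0:
        raise ModelError(
            f"retirement_rate + other_rates = {removal_rate:.4f} > 1 "
            f"at year {state.year} would drive stocks negative"
        )
    removed = removal_rate * s.physicians
    s.physicians = s.physicians - removed
    s.cumulative_exits += float(removed.sum())

    s.year = state.year + 1
    s.validate()
    return s


def simulate(scenario: Scenario) -> Trajectory:
    """Run the engine from baseline to horizon, snapshotting every year."""
    state = scenario.initial_state.copy()
    if scenario.grad_school_return and state.grad_school is None:
        state.grad_school = np.zeros((scenario.grad_school_delay, 2))
    states = [state]
    for year in range(scenario.baseline_year, scenario.horizon_year):
        try:
            state = step(
                state,
                scenario.parameters,
                grad_school_return=scenario.grad_school_return,
                grad_school_delay=scenario.grad_school_delay,
                absolute_inflow=scenario.absolute_inflow,
            )
        except ModelError as exc:
            raise ModelError(f"simulation failed stepping {year}->{year + 1}: "
                             f"{exc}") from exc
        states.append(state)
    return Trajectory(states=states, report_years=list(scenario.report_years))


def backcast(scenario: Scenario, start_year: int, end_year: int) -> Trajectory:
    """Run the same engine over a historical window for validation.

    ``scenario.initial_state`` must describe the system at
    ``start_year``; every year in the window is reported so observed
    series on any sub-grid (e.g. biennial surveys) can be aligned.
    """
    if scenario.initial_state.year != start_year:
        raise ModelError(
            f"backcast initial state is for year "
            f"{scenario.initial_state.year}, expected {start_year}"
        )
    window = replace(
        scenario,
        baseline_year=start_year,
        horizon_year=end_year,
        report_years=list(range(start_year, end_year + 1)),
    )
    return simulate(window)
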