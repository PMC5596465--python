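"""Backcast validation: per-year relative errors, RMSE and the 0.1 gate.

A supply model is judged usable for forecasting when a backcast over a
historical window reproduces the observed physician counts closely:
for each comparison year the relative error e_t = |yhat_t - y_t| / y_t
is computed, and the model passes when the root mean square of the
relative errors falls below a threshold (0.1 by convention in the
system-dynamics health-workforce literature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RMSE_THRESHOLD = 0.1


@dataclass
class ValidationReport:
    """Per-year backcast errors and the aggregate accuracy verdict."""

    years: list[int]
    observed: list[float]
    simulated: list[float]
    relative_errors: list[float]
    rmse: float
    threshold: float = DEFAULT_RMSE_THRESHOLD
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.observed) == len(self.simulated)
                == len(self.relative_errors) == n):
            raise ValueError("per-year fields must have equal length")
        self.passed = self.rmse < self.threshold

    def to_frame(self) -> pd.DataFrame:
        """Wide comparison table: one column per year, rows historic /
        simulated / relative error."""
        return pd.DataFrame(
            [self.observed, self.simulated, self.relative_errors],
            index=["historic", "simulated", "relative_error"],
            columns=self.years,
        ).rename_axis(columns="year")


def relative_error(simulated: float, observed: float) -> float:
    """|yhat - y| / y, the scale-free per-year backcast error."""
    if observed <= 0:
        raise ValueError(
            f"relative error undefined for observed <= 0 (got {observed})"
        )
    return abs(simulated - observed) / observed


def rmse(errors) -> float:
    """Root mean square of a list of relative errors."""
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("rmse of an empty error list is undefined")
    if (e < 0).any():
        raise ValueError("relative errors must be non-negative")
    return float(np.sqrt(np.mean(e**2)))


def validate(
    simulated_series: pd.Series,
    observed_series: pd.Series,
    threshold: float = DEFAULT_RMSE_THRESHOLD,
) -> ValidationReport:
    """Compare a backcast against an observed series year by year.

    Both series are indexed by calendar year; the comparison runs over
    the observed years, which must all be present in the simulated
    series (the backcast reports every year, so biennial survey data
    align naturally).
    """
    obs = observed_series.astype(float).sort_index()
    sim = simulated_series.astype(float)
    missing = [int(y) for y in obs.index if y not in sim.index]
    if missing:
        raise ValueError(
            f"simulated series missing validation years: {missing}"
        )
    if (obs <= 0).any():
        bad = [int(y) for y, v in obs.items() if v <= 0]
        raise ValueError(f"observed headcount must be > 0 (years {bad})")
    years = [int(y) for y in obs.index]
    errors = [relative_error(float(sim.loc[y]), float(obs.loc[y]))
              for y in years]
    return ValidationReport(
        years=years,
        observed=[float(obs.loc[y]) for y in years],
        simulated=[float(sim.loc[y]) for y in years],
        relative_errors=errors,
        rmse=rmse(errors),
        threshold=threshold,
    )


def estimate_retirement_rate(
    historic_totals: pd.Series,
    known_entries: pd.Series,
    clamp: bool = False,
) -> float:
    """Recover an annual retirement/attrition rate from trend data.

    Given observed totals P_t and the known number of entries during
    each year, the implied per-year rate is
    r_t = 1 - (P_{t+1} - entries_t) / P_t, averaged over the window.
    An implied rate outside [0, 1] is reported with a warning and
    clamped only on request.
    """
    totals = historic_totals.astype(float).sort_index()
    if len(totals) < 2:
        raise ValueError("need at least two consecutive years of totals")
    if (totals <= 0).any():
        raise ValueError("historic totals must be positive")
    years = list(totals.index)
    rates = []
    for t, t_next in zip(years[:-1], years[1:]):
        entries = float(known_entries.get(t, 0.0))
        rates.append(1.0 - (totals.loc[t_next] - entries) / totals.loc[t])
    r = float(np.mean(rates))
    if not 0.0 <= r <= 1.0:
        warnings.warn(
            f"implied retirement rate {r:.4f} outside [0, 1]; "
            "check entry accounting", stacklevel=2,
        )
        if clamp:
            r = float(np.clip(r, 0.0, 1.0))
    return r
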