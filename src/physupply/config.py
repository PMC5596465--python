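"""File-format layer: scenario YAML, parameter/population/required CSVs.

All CSVs are UTF-8 with a header row and "." decimal separator.  The
parameter table is stored long (year, parameter, value) with the SMSA
option rates in their own CSV (region_id, rate); the scenario YAML
holds the time grid, pipeline durations, engine options and the full
initial stock state.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PARAMETER_COLUMNS, ParameterTable, Scenario, StockState


def save_parameters(
    params: ParameterTable, rates_path: str | Path, options_path: str | Path
) -> None:
    long = (params.rates.rename_axis(index="year")
            .reset_index()
            .melt(id_vars="year", var_name="parameter", value_name="value")
            .sort_values(["parameter", "year"]))
    long.to_csv(rates_path, index=False)
    (params.smsa_option_rates.rename("rate").rename_axis("region_id")
     .reset_index().to_csv(options_path, index=False))


def load_parameters(
    rates_path: str | Path, options_path: str | Path
) -> ParameterTable:
    long = pd.read_csv(rates_path, float_precision="round_trip")
    rates = long.pivot(index="year", columns="parameter", values="value")
    missing = [c for c in PARAMETER_COLUMNS if c not in rates.columns]
    if missing:
        raise ValueError(
            f"{rates_path}: missing parameters {missing}"
        )
    options = pd.read_csv(options_path, float_precision="round_trip").set_index("region_id")["rate"]
    return ParameterTable(
        rates=rates[list(PARAMETER_COLUMNS)], smsa_option_rates=options
    )


def _state_to_dict(state: StockState) -> dict:
    d = {
        "year": int(state.year),
        "students": state.students.tolist(),
        "residents": state.residents.tolist(),
        "physicians": {str(k): float(v)
                       for k, v in state.physicians.items()},
        "physicians_external": float(state.physicians_external),
        "cumulative_exits": float(state.cumulative_exits),
    }
    if state.grad_school is not None:
        d["grad_school"] = state.grad_school.tolist()
    return d


def _state_from_dict(d: dict) -> StockState:
    return StockState(
        year=int(d["year"]),
        students=np.asarray(d["students"], dtype=float),
        residents=np.asarray(d["residents"], dtype=float),
        physicians=pd.Series(d["physicians"], dtype=float),
        physicians_external=float(d.get("physicians_external", 0.0)),
        cumulative_exits=float(d.get("cumulative_exits", 0.0)),
        grad_school=(np.asarray(d["grad_school"], dtype=float)
                     if "grad_school" in d else None),
    )


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "baseline_year": int(scenario.baseline_year),
        "horizon_year": int(scenario.horizon_year),
        "report_years": [int(y) for y in scenario.report_years],
        "school_duration": int(scenario.school_duration),
        "residency_duration": int(scenario.residency_duration),
        "grad_school_return": bool(scenario.grad_school_return),
        "grad_school_delay": int(scenario.grad_school_delay),
        "initial_state": _state_to_dict(scenario.initial_state),
    }
    if scenario.absolute_inflow is not None:
        doc["absolute_inflow"] = {
            int(y): float(v) for y, v in scenario.absolute_inflow.items()
        }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
    )


def load_scenario(path: str | Path, parameters: ParameterTable) -> Scenario:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    inflow = doc.get("absolute_inflow")
    return Scenario(
        baseline_year=int(doc["baseline_year"]),
        horizon_year=int(doc["horizon_year"]),
        report_years=[int(y) for y in doc["report_years"]],
        school_duration=int(doc.get("school_duration", 6)),
        residency_duration=int(doc.get("residency_duration", 2)),
        grad_school_return=bool(doc.get("grad_school_return", False)),
        grad_school_delay=int(doc.get("grad_school_delay", 4)),
        initial_state=_state_from_dict(doc["initial_state"]),
        parameters=parameters,
        absolute_inflow=(None if inflow is None
                         else pd.Series(inflow, dtype=float)),
    )


def load_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(path, df, ["region_id", "year", "population"])
    return df


def load_required(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(path, df, ["region_id", "year", "required"])
    return df


def load_observed(path: str | Path) -> pd.Series:
    """Observed historic totals (year, headcount) for validation."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(path, df, ["year", "headcount"])
    return df.set_index("year")["headcount"].astype(float)


def _require_columns(path, df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
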