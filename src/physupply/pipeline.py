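"""End-to-end runs: forecast, backcast validation, fixture generation.

Each run is driven by a YAML run config naming its input files, so a
result can always be traced to the exact inputs that produced it; the
run log records a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import config as cfg
from . import geo, synthetic
from .indicators import build_indicator_table, summary_table
from .model import backcast, simulate
from .validation import DEFAULT_RMSE_THRESHOLD, ValidationReport, validate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and settings for one reproducible run (all paths resolved
    relative to the config file's directory)."""

    scenario: Path
    parameters: Path
    option_rates: Path
    population: Path
    required: Path
    out_dir: Path
    geometries: Path | None = None
    historic: Path | None = None
    historic_scenario: Path | None = None
    correction: float = 1.0
    rmse_threshold: float = DEFAULT_RMSE_THRESHOLD
    bins: str = "binary"
    source_text: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        base = path.parent

        def resolve(key, required=True):
            value = doc.get(key)
            if value is None:
                if required:
                    raise ValueError(f"{path}: missing required key {key!r}")
                return None
            return (base / value).resolve()

        run = cls(
            scenario=resolve("scenario"),
            parameters=resolve("parameters"),
            option_rates=resolve("option_rates"),
            population=resolve("population"),
            required=resolve("required"),
            out_dir=resolve("out_dir"),
            geometries=resolve("geometries", required=False),
            historic=resolve("historic", required=False),
            historic_scenario=resolve("historic_scenario", required=False),
            correction=float(doc.get("correction", 1.0)),
            rmse_threshold=float(
                doc.get("rmse_threshold", DEFAULT_RMSE_THRESHOLD)
            ),
            bins=str(doc.get("bins", "binary")),
            source_text=text,
        )
        for name in ("scenario", "parameters", "option_rates",
                     "population", "required", "geometries", "historic",
                     "historic_scenario"):
            p = getattr(run, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        return run

    def hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, exc) from exc
    return wrap


def run_forecast(run: RunConfig) -> Path:
    """simulate -> indicators -> summary -> geographic export.

    Writes trajectory.csv (tidy stocks), indicators.csv, summary.csv
    (wide prefecture report with percent change), regions.geojson when
    geometries are supplied, and run.log with the config hash.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: {run.hash()}"]

    params = _stage("load-parameters")(
        cfg.load_parameters, run.parameters, run.option_rates
    )
    scenario = _stage("load-scenario")(cfg.load_scenario, run.scenario, params)
    populations = _stage("load-population")(cfg.load_population,
                                            run.population)
    required = _stage("load-required")(cfg.load_required, run.required)

    trajectory = _stage("simulate")(simulate, scenario)
    trajectory.to_tidy().to_csv(out / "trajectory.csv", index=False)
    log_lines.append("stage simulate: ok")

    indicators = _stage("indicators")(
        build_indicator_table, trajectory, populations, required,
        run.correction,
    )
    indicators.to_csv(out / "indicators.csv", index=False)
    summary = summary_table(indicators)
    summary.to_csv(out / "summary.csv")
    log_lines.append("stage indicators: ok")

    if run.geometries is not None:
        geometries = _stage("read-geometries")(geo.read_geometries,
                                               run.geometries)
        features = _stage("geo-join")(geo.join_indicators, geometries,
                                      indicators, run.bins)
        geo.write_features(features, out / "regions.geojson")
        log_lines.append("stage geo-export: ok")

    (out / "run.log").write_text("\n".join(log_lines) + "\n",
                                 encoding="utf-8")
    (out / "resolved_config.yaml").write_text(run.source_text,
                                              encoding="utf-8")
    return out


def run_validation(run: RunConfig) -> ValidationReport:
    """Backcast over the historic window and gate on the RMSE.

    Writes validation.csv in the historic-vs-simulated comparison
    layout (rows: historic, simulated, relative error; footer rows:
    rmse and pass/fail).
    """
    if run.historic is None or run.historic_scenario is None:
        raise StageError(
            "load-historic",
            ValueError("run config needs 'historic' and "
                       "'historic_scenario' for validation"),
        )
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = _stage("load-parameters")(
        cfg.load_parameters, run.parameters, run.option_rates
    )
    scenario = _stage("load-historic-scenario")(
        cfg.load_scenario, run.historic_scenario, params
    )
    observed = _stage("load-historic")(cfg.load_observed, run.historic)
    trajectory = _stage("backcast")(
        backcast, scenario, scenario.baseline_year, scenario.horizon_year
    )
    report = _stage("validate")(
        validate, trajectory.annual_totals(), observed, run.rmse_threshold
    )
    frame = report.to_frame()
    lines = [",".join(["row"] + [str(y) for y in report.years])]
    for name in ("historic", "simulated", "relative_error"):
        lines.append(",".join([name] + [repr(v) for v in frame.loc[name]]))
    lines.append(f"rmse,{report.rmse!r}")
    lines.append(f"passed,{report.passed}")
    (out / "validation.csv").write_text("\n".join(lines) + "\n",
                                        encoding="utf-8")
    return report


def run_make_fixtures(
    profile: synthetic.SyntheticProfile, out_dir: str | Path
) -> Path:
    """Materialise a complete, internally consistent input directory.

    The directory is directly loadable by :func:`run_forecast` and
    :func:`run_validation` through the written ``run.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = synthetic.generate_parameters(profile)
    scenario = synthetic.make_scenario(profile, params)
    regions = synthetic.generate_regions(profile)
    required = synthetic.generate_required(
        profile, regions, scenario.initial_state
    )
    validation_years = [
        y for y in range(profile.baseline_year - 12,
                         profile.baseline_year - 1)
        if y % 2 == 0
    ]
    historic = synthetic.generate_historic(profile, params, validation_years)
    hist_scen = synthetic.historic_scenario(
        profile, params, validation_years[0], validation_years[-1]
    )
    geometries = synthetic.generate_geometries(profile.n_regions,
                                               profile.seed)

    cfg.save_parameters(params, out / "parameters.csv",
                        out / "option_rates.csv")
    cfg.save_scenario(scenario, out / "scenario.yaml")
    cfg.save_scenario(hist_scen, out / "historic_scenario.yaml")
    regions.to_csv(out / "population.csv", index=False)
    required.to_csv(out / "required.csv", index=False)
    historic["total"].rename("headcount").rename_axis("year").reset_index() \
        .to_csv(out / "historic.csv", index=False)
    feature_set = geo.RegionFeatureSet(features=[
        {
            "type": "Feature",
            "geometry": geo.mapping(g),
            "properties": {"region_id": rid},
        }
        for rid, g in geometries.items()
    ])
    geo.write_features(feature_set, out / "regions.geojson")

    run_yaml = {
        "scenario": "scenario.yaml",
        "parameters": "parameters.csv",
        "option_rates": "option_rates.csv",
        "population": "population.csv",
        "required": "required.csv",
        "geometries": "regions.geojson",
        "historic": "historic.csv",
        "historic_scenario": "historic_scenario.yaml",
        "out_dir": "output",
        "correction": 1.0,
        "rmse_threshold": DEFAULT_RMSE_THRESHOLD,
    }
    (out / "run.yaml").write_text(
        yaml.safe_dump(run_yaml, sort_keys=False), encoding="utf-8"
    )
    return out
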