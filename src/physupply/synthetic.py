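"""Synthetic inputs with known ground truth for the full pipeline.

Real physician-supply inputs (ministry survey aggregates: headcounts by
sub-region, career-path rates, required numbers, population
projections) are not openly redistributable, so every input the
pipeline needs is generated here at realistic magnitudes: a
Hokkaido-like prefecture of ~5.5 million residents and ~12 000
physicians split across ~20 secondary medical service areas, with
population and physicians concentrated in one dominant urban region and
depopulation in the periphery.

Generation is deterministic per (profile, seed); the "self-consistent"
historic mode produces observed series by running the forecasting
engine itself, so validation round trips are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .model import (
    PARAMETER_COLUMNS,
    ParameterTable,
    Scenario,
    StockState,
    backcast,
)

#: default career-path rates; stay rates reflect the reported retention
#: gap between regional-quota graduates (83.3%) and their peers (45.3%).
DEFAULT_RATES = {
    "pass_rate": 0.90,
    "match_rate": 0.95,
    "grad_school_rate": 0.05,
    "nonclinical_rate": 0.02,
    "stay_rate_general": 0.453,
    "stay_rate_regional": 0.833,
    "other_pref_rate": 0.547,
    "inflow_rate": 0.002,
    "outflow_rate": 0.01,
    "retirement_rate": 0.03,
    "other_rates": 0.005,
}
#: ~three medical schools' combined general intake per year
DEFAULT_GENERAL_QUOTA = 270.0
DEFAULT_REGIONAL_QUOTA_MAX = 30.0


@dataclass
class SyntheticProfile:
    """Knobs of the synthetic prefecture; defaults emulate Hokkaido 2010."""

    n_regions: int = 20
    total_physicians_baseline: float = 12_019.0
    total_population_baseline: float = 5.5e6
    #: fraction of physicians (and population) in the dominant region
    concentration: float = 0.45
    #: fraction of regions constructed to be under-sufficient at baseline
    shortage_fraction: float = 0.2
    #: multiplicative (lognormal-style) noise on historic series
    noise_sd: float = 0.0
    seed: int = 0
    baseline_year: int = 2010
    horizon_year: int = 2030
    #: baseline prefecture-level sufficiency used to set the
    #: prefecture required number (Table-3-like shortage at baseline)
    prefecture_sufficiency: float = 0.88
    #: annual medical-school intakes; the regional quota ramps from its
    #: 1997 introduction up to its full size
    general_quota: float = DEFAULT_GENERAL_QUOTA
    regional_quota_max: float = DEFAULT_REGIONAL_QUOTA_MAX

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name in ("concentration", "shortage_fraction", "noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        if self.total_physicians_baseline <= 0:
            raise ValueError("total_physicians_baseline must be positive")
        if self.total_population_baseline <= 0:
            raise ValueError("total_population_baseline must be positive")
        if self.general_quota < 0 or self.regional_quota_max < 0:
            raise ValueError("quota intakes must be non-negative")

    @property
    def report_years(self) -> list[int]:
        return list(range(self.baseline_year, self.horizon_year + 1, 5))

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]


def _rng(profile: SyntheticProfile, stream: int) -> np.random.Generator:
    # independent substream per generator function, all derived from the seed
    return np.random.default_rng([profile.seed, stream])


def _population_shares(profile: SyntheticProfile) -> pd.Series:
    """Baseline population share per region; R01 is the dominant region."""
    rng = _rng(profile, 1)
    n = profile.n_regions
    if n == 1:
        return pd.Series([1.0], index=profile.region_ids)
    weights = rng.uniform(0.5, 1.5, size=n - 1)
    rest = (1.0 - profile.concentration) * weights / weights.sum()
    return pd.Series(
        np.concatenate([[profile.concentration], rest]),
        index=profile.region_ids,
    )


def generate_regions(profile: SyntheticProfile) -> pd.DataFrame:
    """Region set with populations at every report year.

    The dominant region holds and slightly grows its population; the
    periphery depopulates a few percent per five-year period.  Returns
    a long DataFrame (region_id, year, population).
    """
    rng = _rng(profile, 2)
    shares = _population_shares(profile)
    baseline = shares * profile.total_population_baseline
    n = profile.n_regions
    # per-5-year growth multipliers: >=1 for the dominant region,
    # mild decline elsewhere
    growth = np.concatenate([
        [1.0 + rng.uniform(0.000, 0.015)],
        1.0 - rng.uniform(0.02, 0.06, size=n - 1),
    ]) if n > 1 else np.array([1.0])
    records = []
    for k, year in enumerate(profile.report_years):
        pops = baseline.to_numpy() * growth**k
        records.extend(
            (rid, year, float(p)) for rid, p in zip(profile.region_ids, pops)
        )
    return pd.DataFrame(records, columns=["region_id", "year", "population"])


def _physician_shares(profile: SyntheticProfile) -> pd.Series:
    """Baseline physician share per region (concentration in R01).

    Outside the dominant region, physicians follow population with a
    seeded lognormal dispersion of physicians-per-capita (sd ~0.25),
    producing the regional density inequality (baseline Gini on the
    order of 0.1) that characterises real prefectures.
    """
    shares = _population_shares(profile)
    if profile.n_regions == 1:
        return shares
    rng = _rng(profile, 5)
    jitter = np.exp(rng.normal(0.0, 0.25, size=profile.n_regions - 1))
    rest = shares.iloc[1:] * jitter
    rest = rest / rest.sum()
    out = shares.copy()
    out.iloc[0] = profile.concentration
    out.iloc[1:] = (1.0 - profile.concentration) * rest
    return out


def generate_parameters(profile: SyntheticProfile) -> ParameterTable:
    """Parameter table covering 1990 through five years past the horizon.

    Rates are constant at :data:`DEFAULT_RATES`; the regional quota
    ramps up from its 1997 introduction to its full size.  SMSA option
    rates follow the baseline physician shares (new physicians settle
    where practices already are), so they carry the urban tilt.
    """
    years = range(1990, profile.horizon_year + 6)
    rows = []
    for y in years:
        regional = (
            0.0 if y < 1997
            else min(2.0 * (y - 1996), profile.regional_quota_max)
        )
        row = {"general_quota": profile.general_quota,
               "regional_quota": regional}
        row.update(DEFAULT_RATES)
        rows.append(row)
    rates = pd.DataFrame(rows, index=pd.Index(years, name="year"))
    rates = rates[list(PARAMETER_COLUMNS)]
    return ParameterTable(
        rates=rates, smsa_option_rates=_physician_shares(profile)
    )


def generate_baseline_state(
    profile: SyntheticProfile,
    params: ParameterTable,
    year: int | None = None,
    total_physicians: float | None = None,
    school_duration: int = 6,
    residency_duration: int = 2,
) -> StockState:
    """Stock state at ``year`` consistent with the parameter table.

    Student and resident cohorts are filled from the quota intakes of
    their entry years; the external pool is the rest-of-country stock,
    set to 24x the prefecture stock (national scale relative to a
    prefecture holding ~4% of the country's physicians).
    """
    year = profile.baseline_year if year is None else year
    total = (profile.total_physicians_baseline
             if total_physicians is None else total_physicians)
    students = np.zeros((school_duration, 2))
    for i in range(school_duration):
        row = params.at(year - 1 - i)
        students[i] = (row["general_quota"], row["regional_quota"])
    residents = np.zeros((residency_duration, 2))
    for i in range(residency_duration):
        row = params.at(year - 1 - i)
        intake = np.array([row["general_quota"], row["regional_quota"]])
        residents[i] = (
            intake * row["pass_rate"] * (1 - row["grad_school_rate"])
            * (1 - row["nonclinical_rate"]) * row["match_rate"]
        )
    physicians = _physician_shares(profile) * total
    return StockState(
        year=year,
        students=students,
        residents=residents,
        physicians=physicians,
        physicians_external=24.0 * total,
        cumulative_exits=0.0,
    )


def make_scenario(
    profile: SyntheticProfile, params: ParameterTable | None = None
) -> Scenario:
    """Forecast scenario from baseline to horizon on the 5-year grid."""
    params = generate_parameters(profile) if params is None else params
    return Scenario(
        baseline_year=profile.baseline_year,
        horizon_year=profile.horizon_year,
        report_years=profile.report_years,
        initial_state=generate_baseline_state(profile, params),
        parameters=params,
    )


def historic_scenario(
    profile: SyntheticProfile,
    params: ParameterTable,
    start_year: int,
    end_year: int,
) -> Scenario:
    """Backcast scenario over a historical window.

    The historical stock at the window start is the baseline stock
    scaled back by a steady ~0.7%/year growth trend, mirroring the slow
    secular growth in physician numbers.
    """
    growth = 1.007
    total = profile.total_physicians_baseline / growth ** (
        profile.baseline_year - start_year
    )
    return Scenario(
        baseline_year=start_year,
        horizon_year=end_year,
        report_years=list(range(start_year, end_year + 1)),
        initial_state=generate_baseline_state(
            profile, params, year=start_year, total_physicians=total
        ),
        parameters=params,
    )


def generate_historic(
    profile: SyntheticProfile,
    params: ParameterTable,
    years: list[int],
) -> pd.DataFrame:
    """Observed historic physician counts (per region plus total).

    With ``noise_sd == 0`` the series is exactly the engine's own
    backcast over the window (self-consistent mode: validating the
    engine against it gives RMSE 0).  With noise, each observation is
    multiplied by exp(N(0, noise_sd)) — proportional survey error that
    never produces negative headcounts.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("generate_historic needs a non-empty year list")
    scen = historic_scenario(profile, params, years[0], years[-1])
    traj = backcast(scen, years[0], years[-1])
    table = traj.totals_by_region().loc[years]
    if profile.noise_sd > 0:
        rng = _rng(profile, 3)
        table = table * np.exp(
            rng.normal(0.0, profile.noise_sd, size=table.shape)
        )
    # C-contiguous row sums reduce in the same order as summing each
    # region Series, keeping the noiseless round trip bit-exact
    table["total"] = np.sum(np.ascontiguousarray(table.to_numpy()), axis=1)
    return table


def generate_required(
    profile: SyntheticProfile,
    regions: pd.DataFrame,
    baseline_state: StockState,
) -> pd.DataFrame:
    """Required physician numbers per region and for the prefecture.

    Constructed so that, at baseline and with correction coefficient 1,
    exactly ``round(shortage_fraction * n_regions)`` regions (the
    lowest-density ones) sit below sufficiency 1, and the prefecture
    overall sits at ``prefecture_sufficiency``.  Requirements are held
    constant across report years, as in a single-survey snapshot.
    Returns a long DataFrame (region_id, year, required) including
    prefecture rows.
    """
    from .indicators import PREFECTURE

    n = profile.n_regions
    k = int(round(profile.shortage_fraction * n))
    base_pop = (regions[regions["year"] == profile.baseline_year]
                .set_index("region_id")["population"])
    phys = baseline_state.physicians
    density = phys / base_pop.loc[phys.index] * 100_000
    shortage_ids = set(density.nsmallest(k).index)
    records = []
    for year in profile.report_years:
        for rid in phys.index:
            target = 0.90 if rid in shortage_ids else 1.15
            records.append((rid, year, float(phys.loc[rid] / target)))
        records.append((
            PREFECTURE, year,
            float(phys.sum() / profile.prefecture_sufficiency),
        ))
    return pd.DataFrame(records, columns=["region_id", "year", "required"])


def generate_geometries(
    n_regions: int, seed: int = 0
) -> dict[str, Polygon]:
    """Toy non-overlapping rectangular tiles standing in for SMSA
    boundaries, placed on a lon-lat grid near 141E 43N.

    The tiles are synthetic stand-ins, not real administrative
    boundaries; a small seeded jitter varies their sizes.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng([seed, 4])
    cols = int(np.ceil(np.sqrt(n_regions)))
    tiles = {}
    for i in range(n_regions):
        r, c = divmod(i, cols)
        x0 = 140.0 + c * 1.2
        y0 = 42.0 + r * 1.2
        w, h = rng.uniform(0.8, 1.0, size=2)
        tiles[f"R{i + 1:02d}"] = box(x0, y0, x0 + w, y0 + h)
    return tiles
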