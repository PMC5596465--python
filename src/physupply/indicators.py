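"""Regional supply-demand indicators: density, sufficiency, Gini.

For each sub-region (SMSA) and report year the pipeline derives

* density — practising physicians per 100 000 residents,
* sufficiency level — forecast headcount over the surveyed required
  headcount, times a correction coefficient reconciling an
  all-physician forecast with a hospital-only requirement; a region
  with sufficiency >= 1 is classified sufficient, otherwise shortage,
* an unweighted Gini coefficient of the regional densities per year,
  Gini = (1 / 2 n^2 mu) * sum_i sum_j |y_i - y_j|, measuring
  maldistribution across sub-regions (each region counts once,
  regardless of its population).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import Trajectory

logger = logging.getLogger(__name__)

#: region_id sentinel for whole-prefecture rows in indicator tables
PREFECTURE = "PREFECTURE"

SUFFICIENT = "sufficient"
SHORTAGE = "shortage"


def density_per_100k(physicians: float, population: float) -> float:
    """Practising physicians per 100 000 residents."""
    if population <= 0:
        raise ValueError(f"population must be > 0 (got {population})")
    return physicians / population * 100_000


def correction_coefficient(
    hospital_physicians: float,
    clinic_physicians: float,
    mode: str = "hospital_share",
) -> float:
    """Adjustment aligning an all-physician forecast with a
    hospital-based required number.

    The required numbers come from hospital surveys and exclude
    clinics, while the forecast counts all practising physicians.  The
    default ``hospital_share`` mode returns hospital / (hospital +
    clinic), scaling the forecast down to its hospital component;
    ``hospital_to_clinic`` returns the literal quotient
    hospital / clinic for users who read the staffing split that way.
    """
    if hospital_physicians < 0 or clinic_physicians < 0:
        raise ValueError("headcounts must be non-negative")
    if hospital_physicians + clinic_physicians == 0:
        raise ValueError("at least one headcount must be positive")
    if mode == "hospital_share":
        return hospital_physicians / (hospital_physicians + clinic_physicians)
    if mode == "hospital_to_clinic":
        if clinic_physicians == 0:
            raise ValueError("hospital_to_clinic undefined with zero "
                             "clinic physicians")
        return hospital_physicians / clinic_physicians
    raise ValueError(f"unknown correction mode: {mode!r}")


def sufficiency_level(
    forecast: float, required: float, correction: float = 1.0
) -> float:
    """forecast / required x correction; >= 1 means the region is staffed."""
    if required <= 0:
        raise ValueError(f"required headcount must be > 0 (got {required})")
    if correction <= 0:
        raise ValueError(f"correction coefficient must be > 0 "
                         f"(got {correction})")
    return forecast / required * correction


def classify(sufficiency: float) -> str:
    """Binary shortage classification; the boundary 1.0 is sufficient."""
    if sufficiency < 0:
        raise ValueError(f"sufficiency must be >= 0 (got {sufficiency})")
    return SUFFICIENT if sufficiency >= 1.0 else SHORTAGE


def gini(densities) -> float:
    """Unweighted Gini coefficient of regional densities.

    Mean absolute pairwise difference normalised by twice the mean:
    (1 / 2 n^2 mu) * sum_i sum_j |y_i - y_j|, in [0, (n-1)/n].
    Computed via the sorted-rank identity, O(n log n).
    """
    y = np.asarray(list(densities), dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("gini of an empty density vector is undefined")
    if (y < 0).any():
        raise ValueError("densities must be non-negative")
    mu = y.mean()
    if mu == 0:
        logger.warning("gini of an all-zero density vector: returning 0")
        return 0.0
    ys = np.sort(y)
    ranks = np.arange(1, n + 1)
    # sum_ij |y_i - y_j| = 2 * sum_i (2i - n - 1) y_(i)
    return float(np.sum((2 * ranks - n - 1) * ys) / (n**2 * mu))


def percent_change(v_start: float, v_end: float) -> float:
    """100 x (v_end - v_start) / v_start."""
    if v_start == 0:
        raise ValueError("percent change undefined from a zero start value")
    return 100.0 * (v_end - v_start) / v_start


def build_indicator_table(
    trajectory: Trajectory,
    populations: pd.DataFrame,
    required: pd.DataFrame,
    correction: float = 1.0,
) -> pd.DataFrame:
    """Assemble the tidy per-region, per-report-year indicator table.

    Parameters
    ----------
    trajectory
        Simulation output; its report years define the table's years.
    populations
        Long DataFrame (region_id, year, population) covering every
        region at every report year.
    required
        Long DataFrame (region_id, year, required); must include
        :data:`PREFECTURE` rows for the prefecture-level requirement
        (the prefecture sufficiency uses its own surveyed number, not
        the sum of the regional rows).
    correction
        Correction coefficient applied to every sufficiency level.

    Returns a DataFrame with columns region_id, year, physicians,
    population, density, required, sufficiency, status, gini — the
    per-year Gini (over regional densities) is carried on the
    prefecture row.
    """
    totals = trajectory.totals_by_region()
    regions = list(totals.columns)
    pop = populations.set_index(["region_id", "year"])["population"]
    req = required.set_index(["region_id", "year"])["required"]

    def lookup(table: pd.Series, what: str, region: str, year: int) -> float:
        try:
            return float(table.loc[(region, year)])
        except KeyError:
            raise KeyError(
                f"missing {what} for region {region!r}, year {year}"
            ) from None

    records = []
    for year in trajectory.report_years:
        densities = {}
        for region in regions:
            phys = float(totals.loc[year, region])
            p = lookup(pop, "population", region, year)
            r = lookup(req, "required number", region, year)
            d = density_per_100k(phys, p)
            s = sufficiency_level(phys, r, correction)
            densities[region] = d
            records.append((region, year, phys, p, d, r, s, classify(s),
                            np.nan))
        g = gini(list(densities.values()))
        phys_total = float(totals.loc[year].sum())
        pop_total = sum(lookup(pop, "population", r, year) for r in regions)
        req_pref = lookup(req, "required number", PREFECTURE, year)
        s_pref = sufficiency_level(phys_total, req_pref, correction)
        records.append((
            PREFECTURE, year, phys_total, pop_total,
            density_per_100k(phys_total, pop_total), req_pref, s_pref,
            classify(s_pref), g,
        ))
    return pd.DataFrame(
        records,
        columns=["region_id", "year", "physicians", "population", "density",
                 "required", "sufficiency", "status", "gini"],
    )


def summary_table(indicators: pd.DataFrame) -> pd.DataFrame:
    """Prefecture-level wide report: headcount, sufficiency, density and
    Gini by report year, plus the percent change from the first to the
    last report year.

    Rounding (headcount to integer, density and sufficiency to two
    decimals, Gini to three, percent change to one) happens here, at
    report time only.
    """
    pref = (indicators[indicators["region_id"] == PREFECTURE]
            .set_index("year").sort_index())
    years = list(pref.index)
    rows = {
        "physicians": pref["physicians"],
        "sufficiency": pref["sufficiency"],
        "density": pref["density"],
        "gini": pref["gini"],
    }
    out = pd.DataFrame(rows).T
    # a zero start value (e.g. Gini of a single region) has no defined
    # percent change; report it as missing rather than failing the run
    pct = {
        name: (percent_change(float(series.iloc[0]), float(series.iloc[-1]))
               if float(series.iloc[0]) != 0.0 else np.nan)
        for name, series in rows.items()
    }
    decimals = {"physicians": 0, "sufficiency": 2, "density": 2, "gini": 3}
    for name, nd in decimals.items():
        # round-half-to-even, applied only in this report
        out.loc[name] = out.loc[name].round(nd)
    out["pct_change"] = [round(pct[name], 1) for name in out.index]
    out.loc["physicians", years] = out.loc["physicians", years].astype(float)
    out = out.rename_axis(index="variable", columns=None)
    out.columns = [str(c) for c in out.columns]
    return out
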