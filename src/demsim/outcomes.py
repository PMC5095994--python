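"""Population-level outcome measures: prevalence, mortality burden,
informal caregiving, and sectoral costs.

These operations read the per-year aggregates of a
:class:`~demsim.engine.SimulationResult` and express them as the
standard reporting measures of a dementia burden projection: July-1
point prevalence (counts and per-1000 rates for ages 40+ and 80+, by
sex), dementia deaths and the death rate per 1000 prevalent, mean YLL
and HYLL among each year's dementia decedents, caregiving volumes and
the weekly-hours distribution, and annual costs by health sector (in
millions) split from out-of-pocket expenses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CARE_CATEGORIES, SimulationResult
from .parameters import SECTORS


class RangeError(ValueError):
    """A requested year lies outside the simulated horizon."""


class UndefinedRatioError(ValueError):
    """Growth ratio requested with a zero base value."""


def _row(result: SimulationResult, year: int) -> pd.Series:
    if year not in result.annual.index:
        raise RangeError(
            f"year {year} outside simulated horizon "
            f"{result.annual.index.min()}-{result.annual.index.max()}"
        )
    return result.annual.loc[year]


def _rate(cases, pop) -> float:
    return float(cases / pop * 1000.0) if pop > 0 else float("nan")


def point_prevalence(result: SimulationResult, year: int) -> dict:
    """July-1 dementia counts and per-1000 rates for ages 40+ and 80+."""
    r = _row(result, year)
    return {
        "year": int(year),
        "count": {"total": float(r["dem_mid"]), "male": float(r["dem_mid_m"]),
                  "female": float(r["dem_mid_f"])},
        "rate_40plus": {"total": _rate(r["dem40"], r["pop40"]),
                        "male": _rate(r["dem40_m"], r["pop40_m"]),
                        "female": _rate(r["dem40_f"], r["pop40_f"])},
        "rate_80plus": {"total": _rate(r["dem80"], r["pop80"]),
                        "male": _rate(r["dem80_m"], r["pop80_m"]),
                        "female": _rate(r["dem80_f"], r["pop80_f"])},
    }


def growth_ratio(base_value: float, horizon_value: float) -> float:
    """Horizon-to-base ratio, reported to two decimals."""
    if base_value == 0:
        raise UndefinedRatioError("growth ratio undefined for a zero base value")
    return round(float(horizon_value) / float(base_value), 2)


def mortality_summary(result: SimulationResult, year: int) -> dict:
    """Dementia deaths, death rate per 1000 prevalent, and mean YLL/HYLL.

    YLL and HYLL are weighted means over that year's dementia decedents.
    A nonzero death count over zero prevalence yields an undefined rate
    (flagged, not raised).
    """
    r = _row(result, year)
    deaths = float(r["dem_deaths_w"])
    prev = float(r["dem_mid"])
    dec = float(r["dem_decedents_w"])
    return {
        "year": int(year),
        "deaths": deaths,
        "rate_per_1000": deaths / prev * 1000.0 if prev > 0 else float("nan"),
        "rate_undefined": bool(prev == 0 and deaths > 0),
        "mean_yll": float(r["yll_sum_w"] / dec) if dec > 0 else float("nan"),
        "mean_hyll": float(r["hyll_sum_w"] / dec) if dec > 0 else float("nan"),
    }


def caregiving_summary(result: SimulationResult, year: int) -> dict:
    """Informal-care volumes and the weekly-hours distribution.

    Recipients are July-1 persons with dementia assigned care for the
    year; hours are weight x representative weekly hours x 52, prorated
    over the fraction of the year lived; the per-working-age measure
    divides by the weighted July-1 population aged 25-65 inclusive.
    Bin percentages (including "no care") are over all July-1 persons
    with dementia and sum to 100.
    """
    r = _row(result, year)
    dem = float(r["dem_mid"])
    pct = {}
    for cat in CARE_CATEGORIES:
        pct[cat] = float(r[f"care_{cat}_w"] / dem * 100.0) if dem > 0 else float("nan")
    if dem == 0:
        pct["none"] = 100.0
        for cat in CARE_CATEGORIES[1:]:
            pct[cat] = 0.0
    pop_work = float(r["pop_25_65"])
    hours = float(r["care_hours_w"])
    return {
        "year": int(year),
        "recipients": float(r["care_recipients_w"]),
        "total_hours_per_year": hours,
        "hours_per_person_25_65": hours / pop_work if pop_work > 0 else float("nan"),
        "percent_by_bin": pct,
        "caregiver_total_hours": hours,
        "caregiver_out_of_pocket": float(r["caregiver_oop_w"]),
        "caregiver_mean_hui3": None,  # constant model value; see parameters
    }


def cost_summary(result: SimulationResult, year: int) -> dict:
    """Annual costs among persons with dementia, by sector, in millions.

    The total is exactly the sum of the seven sector costs; out-of-pocket
    expenses are reported separately.
    """
    r = _row(result, year)
    sectors = {s: float(r[f"cost_{s}_w"]) / 1e6 for s in SECTORS}
    return {
        "year": int(year),
        "sectors_millions": sectors,
        "total_millions": float(sum(sectors.values())),
        "out_of_pocket_millions": float(r["cost_oop_w"]) / 1e6,
    }


@dataclass
class AnnualAggregate:
    """All reported measures for one calendar year."""

    year: int
    prevalence: dict
    mortality: dict
    caregiving: dict
    costs: dict

    def validate(self) -> "AnnualAggregate":
        pct = self.caregiving["percent_by_bin"]
        total = sum(v for v in pct.values() if not np.isnan(v))
        if pct and not np.isnan(total) and abs(total - 100.0) > 0.01:
            raise ValueError(f"caregiving bin percentages sum to {total}, not 100")
        s = sum(self.costs["sectors_millions"].values())
        if abs(s - self.costs["total_millions"]) > 1e-9 * max(1.0, abs(s)):
            raise ValueError("total cost does not equal the sector sum")
        return self


def annual_aggregate(result: SimulationResult, year: int) -> AnnualAggregate:
    return AnnualAggregate(
        year=int(year),
        prevalence=point_prevalence(result, year),
        mortality=mortality_summary(result, year),
        caregiving=caregiving_summary(result, year),
        costs=cost_summary(result, year),
    ).validate()


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def prevalence_table(result: SimulationResult, years) -> pd.DataFrame:
    rows = []
    for y in years:
        p = point_prevalence(result, y)
        rows.append({
            "year": y,
            "count_total": p["count"]["total"],
            "count_male": p["count"]["male"],
            "count_female": p["count"]["female"],
            "rate40_total": p["rate_40plus"]["total"],
            "rate40_male": p["rate_40plus"]["male"],
            "rate40_female": p["rate_40plus"]["female"],
            "rate80_total": p["rate_80plus"]["total"],
            "rate80_male": p["rate_80plus"]["male"],
            "rate80_female": p["rate_80plus"]["female"],
        })
    return pd.DataFrame(rows).set_index("year")


def burden_table(result: SimulationResult, years) -> pd.DataFrame:
    rows = []
    for y in years:
        m = mortality_summary(result, y)
        c = caregiving_summary(result, y)
        row = {
            "year": y,
            "deaths": m["deaths"],
            "mortality_rate_per_1000": m["rate_per_1000"],
            "mean_yll": m["mean_yll"],
            "mean_hyll": m["mean_hyll"],
            "care_recipients": c["recipients"],
            "care_hours_millions": c["total_hours_per_year"] / 1e6,
            "care_hours_per_person_25_65": c["hours_per_person_25_65"],
        }
        for cat, v in c["percent_by_bin"].items():
            row[f"pct_{cat}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def cost_table(result: SimulationResult, years) -> pd.DataFrame:
    rows = []
    for y in years:
        c = cost_summary(result, y)
        row = {"year": y, **{s: c["sectors_millions"][s] for s in SECTORS}}
        row["total"] = c["total_millions"]
        row["out_of_pocket"] = c["out_of_pocket_millions"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def write_report(result: SimulationResult, outdir, years=None) -> Path:
    """Emit the three report tables as CSV and aligned text plus a run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if years is None:
        years = list(result.annual.index)
    tables = {
        "prevalence": prevalence_table(result, years),
        "burden": burden_table(result, years),
        "costs": cost_table(result, years),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv")
        (outdir / f"{name}.txt").write_text(df.round(3).to_string() + "\n")
    summary = {
        "scenario": result.scenario_name,
        "n_actors": int(result.n_actors),
        "seed": int(result.seed),
        "weight": float(result.weight),
        "years": [int(years[0]), int(years[-1])],
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return outdir
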