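"""Deterministic cohort-component twin of the microsimulation.

Evolves expected weighted occupancy counts N(age, sex, dementia state)
through exactly the same within-year event ordering as the engine —
entries and emigration at January 1, the onset draw, then survival with
the onset-year hazard prorated around a uniform onset date — so the
microsimulation's expectation equals the oracle *exactly*, not just
asymptotically.  Used to validate runs (z-scores against binomial
sampling error) and to generate synthetic "observed" prevalence for the
calibration harness.

Mid-year (July 1) occupancies use the closed-form within-year survival
integrals; because birth dates are uniform within the birth year, half
of each January-1 age cohort has already had its birthday by July 1,
which the age-stratified outputs account for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .parameters import AGE_MAX, N_AGES, ParameterSet, SEXES

_CAP_AGE = AGE_MAX - 1  # forced death during the year of the 110th birthday


def _phi(x):
    """(1 - exp(-x)) / x, stable near zero."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)


@dataclass
class OracleState:
    """Occupancy and flows for one calendar year."""

    year: int
    occupancy: np.ndarray  # (111, 2, 2): age, sex, dementia — at January 1
    onsets: float
    deaths: float
    dem_deaths: float
    emigrants: float
    dem_emigrants: float


@dataclass
class OracleResult:
    """Annual expected aggregates plus January-1 occupancy series."""

    annual: pd.DataFrame
    strata: pd.DataFrame
    occupancy: np.ndarray  # (n_years + 1, 111, 2, 2)
    years: np.ndarray


@dataclass
class CalibrationReport:
    """Projected vs reference prevalence per (age band, sex)."""

    table: pd.DataFrame  # age_band, sex, projected, reference, ratio
    band: tuple
    calibration_unnecessary: bool
    out_of_band: pd.DataFrame


def _entry_matrix(params: ParameterSet, year: int) -> np.ndarray:
    """Expected weighted dementia-free entrants (age, sex) at January 1."""
    out = np.zeros((N_AGES, 2))
    coh = params.demography.cohorts
    j = (year - 1) - coh.year_start
    if 0 <= j < coh.births.shape[0]:
        out[0, :] += coh.births[j, :]
    mig = params.demography.migration
    j = (year - 1) - mig.year_start
    if 0 <= j < mig.n_years:
        for g in range(mig.immigration.shape[2]):
            lo, hi = mig.arrival_group_age_bounds(g)
            for s in range(2):
                c = mig.immigration[j, s, g]
                if c > 0:
                    out[lo:hi, s] += c / (hi - lo)
    return out


def _hui3_band_probs(params: ParameterSet, dementia: int) -> np.ndarray:
    """P(HUI3 band) per (age, sex) for one dementia state (clipped normal)."""
    cg = params.caregiving
    mu = params.hui3.mean[:, :, dementia]
    sd = params.hui3.sd[:, :, dementia]
    edges = np.asarray(cg.hui3_band_edges)[1:]  # interior edges
    nb = len(cg.hui3_band_edges)
    cdf = np.ones((N_AGES, 2, nb))  # cumulative P(band <= k)
    for k, e in enumerate(edges):
        with np.errstate(divide="ignore", invalid="ignore"):
            zk = np.where(sd > 0, (e - mu) / np.where(sd > 0, sd, 1.0), np.inf)
        cdf[:, :, k] = np.where(sd > 0, norm.cdf(zk), (mu <= e).astype(float))
    probs = np.diff(np.concatenate([np.zeros((N_AGES, 2, 1)), cdf], axis=2), axis=2)
    return probs  # (111, 2, nb)


def run_oracle(params: ParameterSet, scenario=None, horizon: int | None = None) -> OracleResult:
    """Propagate expected occupancies with the engine's event ordering."""
    if scenario is not None:
        from .scenarios import apply_scenario

        params = apply_scenario(params, scenario)
    params.validate()
    meta = params.metadata
    y1 = horizon if horizon is not None else meta.year_end
    coh = params.demography.cohorts
    mig = params.demography.migration
    y0 = min(coh.year_start, mig.year_start) + 1
    years = np.arange(y0, y1 + 1)
    ny = years.size
    min_age = meta.incidence_min_age
    cg = params.caregiving
    ages = np.arange(N_AGES)

    # receipt probability marginalised over the HUI3 band, per (age, sex, d)
    band_p0 = _hui3_band_probs(params, 0)
    band_p1 = _hui3_band_probs(params, 1)
    gi = cg.group_index(ages)
    pr_care = np.empty((N_AGES, 2, 2))
    for s in range(2):
        pr_care[:, s, 0] = np.sum(band_p0[:, s, :] * cg.receipt_prob[gi, 0, :], axis=1)
        pr_care[:, s, 1] = np.sum(band_p1[:, s, :] * cg.receipt_prob[gi, 1, :], axis=1)

    N = np.zeros((N_AGES, 2, 2))
    occ = np.zeros((ny + 1, N_AGES, 2, 2))
    cols = {k: np.zeros(ny) for k in (
        "pop_jan", "prev_jan", "onsets", "deaths", "dem_deaths",
        "emigrants", "dem_emigrants", "entries",
        "pop_mid", "dem_mid", "pop40", "pop80", "dem40", "dem80",
        "free_at_risk", "dem_at_risk", "care_recipients",
    )}
    bands5 = np.arange(40, 90, 5)
    strata_pop = np.zeros((ny, 2, bands5.size))
    strata_dem = np.zeros((ny, 2, bands5.size))

    # carried from the previous year: expected "pending care" mass entering
    # year t per (Jan-1 age in year t-1, sex, state-at-end-of-t-1)
    care_free = np.zeros((N_AGES, 2))  # free survivors of t-1 x receipt prob
    care_dem = np.zeros((N_AGES, 2))  # demented survivors of t-1 x receipt prob

    for j, t in enumerate(years):
        ent = _entry_matrix(params, t)
        N[:, :, 0] += ent
        cols["entries"][j] = ent.sum()
        occ[j] = N
        cols["pop_jan"][j] = N.sum()
        cols["prev_jan"][j] = N[:, :, 1].sum()

        # emigration at January 1
        p_em = -np.expm1(-mig.emigration_year_matrix(t).T)  # (111, 2)
        emig = N * p_em[:, :, None]
        cols["emigrants"][j] = emig.sum()
        cols["dem_emigrants"][j] = emig[:, :, 1].sum()
        N = N - emig
        care_free *= 1.0 - p_em
        care_dem *= 1.0 - p_em

        # onset draw
        inc = params.incidence.year_matrix(t).T  # (111, 2)
        p_on = -np.expm1(-inc)
        p_on[:min_age, :] = 0.0
        O = N[:, :, 0] * p_on
        stay = N[:, :, 0] - O
        cols["onsets"][j] = O.sum()
        cols["free_at_risk"][j] = N[:, :, 0].sum()
        cols["dem_at_risk"][j] = N[:, :, 1].sum() + O.sum()

        # survival with the engine's hazard structure
        A = params.mortality.year_matrix(t).T  # (111, 2)
        B = A * params.hazard_ratio.year_matrix(t).T
        sA = np.exp(-A)
        sB = np.exp(-B)
        sO = np.exp(-B) * _phi(A - B)  # onset date uniform in the year
        cap = ages >= _CAP_AGE
        sA[cap] = 0.0
        sB[cap] = 0.0
        sO[cap] = 0.0

        dem_prev = N[:, :, 1]
        deaths_free = stay * (1.0 - sA)
        deaths_dem = dem_prev * (1.0 - sB) + O * (1.0 - sO)
        cols["deaths"][j] = deaths_free.sum() + deaths_dem.sum()
        cols["dem_deaths"][j] = deaths_dem.sum()

        # July-1 (mid-year) occupancy; at the cap age only actors whose
        # 110th birthday falls after July 1 (half of them) can be alive
        c109 = np.where(cap, 0.5, 1.0)[:, None]
        mid_dem_prev = dem_prev * np.exp(-0.5 * B) * c109
        g_half = np.exp(-0.5 * B) * 0.5 * _phi(0.5 * (A - B))
        mid_dem_onset = O * g_half * c109
        mid_free = stay * np.exp(-0.5 * A) * c109
        mid_onset_total = O * (g_half + 0.5 * np.exp(-0.5 * A)) * c109
        mid_dem = mid_dem_prev + mid_dem_onset
        mid_pop = mid_free + mid_onset_total + mid_dem_prev
        cols["dem_mid"][j] = mid_dem.sum()
        cols["pop_mid"][j] = mid_pop.sum()

        # expected caregiving recipients among the July-1 demented
        rec = (care_dem * np.exp(-0.5 * B) * c109
               + care_free * p_on * g_half * c109)
        cols["care_recipients"][j] = rec.sum()

        # age strata at July 1: half of each Jan-1 age cohort has passed
        # its birthday by mid-year (all of it at the cap age)
        for arr, key40, key80, st in (
            (mid_pop, "pop40", "pop80", strata_pop),
            (mid_dem, "dem40", "dem80", strata_dem),
        ):
            by_mid_age = np.zeros((N_AGES + 1, 2))
            w_lo = np.where(cap, 1.0, 0.5)[:, None]
            np.add.at(by_mid_age, ages, arr * w_lo)
            np.add.at(by_mid_age, ages + 1, arr * (1.0 - w_lo))
            cols[key40][j] = by_mid_age[40:].sum()
            cols[key80][j] = by_mid_age[80:].sum()
            mid_ages = np.arange(N_AGES + 1)
            bi = np.minimum(np.maximum(mid_ages - 40, 0) // 5, bands5.size - 1)
            for s in range(2):
                sel = mid_ages >= 40
                st[j, s] = np.bincount(bi[sel], weights=by_mid_age[sel, s],
                                       minlength=bands5.size)

        # carry expected pending-care mass into next year, and age everyone
        end_free = stay * sA
        end_dem = dem_prev * sB + O * sO
        care_free_next = np.zeros((N_AGES, 2))
        care_dem_next = np.zeros((N_AGES, 2))
        care_free_next[1:, :] = (end_free * pr_care[:, :, 0])[:-1, :]
        care_dem_next[1:, :] = (end_dem * pr_care[:, :, 1])[:-1, :]
        care_free, care_dem = care_free_next, care_dem_next

        N2 = np.zeros_like(N)
        N2[1:, :, 0] = end_free[:-1, :]
        N2[1:, :, 1] = end_dem[:-1, :]
        N = N2
    occ[ny] = N

    annual = pd.DataFrame({"year": years, **cols}).set_index("year")
    rows = []
    for jj, y in enumerate(years):
        for s in range(2):
            for bi, lo in enumerate(bands5):
                hi = lo + 4 if bi < bands5.size - 1 else None
                rows.append((y, SEXES[s], f"{lo}-{hi}" if hi else f"{lo}+",
                             strata_pop[jj, s, bi], strata_dem[jj, s, bi]))
    strata = pd.DataFrame(rows, columns=["year", "sex", "age_band", "pop", "dem"])
    return OracleResult(annual=annual, strata=strata, occupancy=occ, years=years)


# ---------------------------------------------------------------------------
# Microsim vs oracle
# ---------------------------------------------------------------------------

#: measure -> (microsim column source, oracle expectation, oracle at-risk)
_MEASURES = {
    "prevalence": ("dem_mid", "dem_mid", "pop_mid"),
    "onsets": ("onsets_w", "onsets", "free_at_risk"),
    "dem_deaths": ("dem_deaths_w", "dem_deaths", "dem_at_risk"),
    "deaths": ("deaths_w", "deaths", "pop_jan"),
    "care_recipients": ("care_recipients_w", "care_recipients", "dem_at_risk"),
}


def compare_microsim_to_oracle(result, oracle: OracleResult,
                               measures=("prevalence", "onsets", "dem_deaths"),
                               years=None, min_expected: float = 5.0) -> pd.DataFrame:
    """Z-scores of microsimulation aggregates against oracle expectations.

    The standard error treats each weighted count as ``weight x Binomial``
    with the pooled success probability implied by the oracle's at-risk
    mass; cells whose expected actor count falls below ``min_expected``
    are excluded (the normal approximation is meaningless there).
    Returns one row per (year, measure) with a ``flag`` where |z| > 3.
    """
    w = result.weight
    mic = result.annual
    orc = oracle.annual
    common = mic.index.intersection(orc.index)
    if years is not None:
        common = common.intersection(pd.Index(years))
    if len(common) == 0:
        raise ValueError("no overlapping years between microsimulation and oracle")
    rows = []
    for m in measures:
        mcol, ocol, rcol = _MEASURES[m]
        for y in common:
            exp = float(orc.loc[y, ocol])
            risk = float(orc.loc[y, rcol])
            if exp / w < min_expected or risk <= 0:
                continue
            p = min(exp / risk, 1.0)
            se = np.sqrt(w * exp * (1.0 - p))
            obs = float(mic.loc[y, mcol])
            z = (obs - exp) / se if se > 0 else 0.0
            rows.append((int(y), m, obs, exp, se, z, abs(z) > 3.0))
    return pd.DataFrame(rows, columns=["year", "measure", "observed", "expected",
                                       "se", "z", "flag"])


# ---------------------------------------------------------------------------
# Calibration harness
# ---------------------------------------------------------------------------


def _band_lower(label: str) -> int:
    return int(label.rstrip("+").split("-")[0])


def prevalence_by_stratum(strata: pd.DataFrame, year: int,
                          lower_bounds=(40, 65, 75, 85)) -> pd.DataFrame:
    """Per-1000 prevalence per (age stratum, sex) at July 1 of one year.

    Strata are cumulative "age X and older" groups (the convention of
    dementia reporting tables), built from the 5-year bands of a
    simulation or oracle ``strata`` table.  Pass 5-year band lower edges
    to get non-cumulative bands instead.
    """
    sub = strata[strata["year"] == year]
    if sub.empty:
        raise ValueError(f"year {year} outside the simulated horizon")
    sub = sub.assign(_lo=[_band_lower(b) for b in sub["age_band"]])
    rows = []
    for lo in lower_bounds:
        grp = sub[sub["_lo"] >= lo]
        for sx, g in grp.groupby("sex"):
            pop, dem = g["pop"].sum(), g["dem"].sum()
            rows.append({
                "age_band": f"{lo}+", "sex": sx,
                "prevalence_per_1000": dem / pop * 1000.0 if pop > 0 else np.nan,
                "pop": pop, "dem": dem,
            })
    return pd.DataFrame(rows)


def calibration_check(projected: pd.DataFrame, reference: pd.DataFrame,
                      band=(0.9, 1.1), min_population: float = 0.0) -> CalibrationReport:
    """Compare projected to reference prevalence per (age band, sex).

    Strata present in both tables are compared as a ratio
    projected / reference; if all ratios fall within ``band`` the report
    carries the "calibration unnecessary" flag.
    """
    key = ["age_band", "sex"]
    merged = projected.merge(reference, on=key, suffixes=("_proj", "_ref"))
    merged = merged[merged["prevalence_per_1000_ref"] > 0]
    if min_population > 0 and "pop_proj" in merged:
        merged = merged[merged["pop_proj"] >= min_population]
    if merged.empty:
        raise ValueError("no overlapping strata between projected and reference")
    merged = merged.assign(
        ratio=merged["prevalence_per_1000_proj"] / merged["prevalence_per_1000_ref"]
    )
    out = merged[key + ["prevalence_per_1000_proj", "prevalence_per_1000_ref", "ratio"]]
    bad = out[(out["ratio"] < band[0]) | (out["ratio"] > band[1])]
    return CalibrationReport(
        table=out.reset_index(drop=True),
        band=tuple(band),
        calibration_unnecessary=bad.empty,
        out_of_band=bad.reset_index(drop=True),
    )
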