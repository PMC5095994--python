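"""Continuous-time microsimulation engine with counterfactual twins.

Each actor's lifecourse is simulated year by year: a dementia-onset
Bernoulli draw at each January 1, death by exact inversion of the
cumulative piecewise-constant hazard against a single per-actor
Exponential(1) threshold, an annual HUI3 value, informal-caregiving
assignment for the following year, and sector cost accrual split between
the incident phase (12 months following onset, prorated across calendar
years) and the prevalent phase.

Every random draw comes from a counter-based stream keyed by
``(master seed, actor id, purpose, calendar year)``, so draws are
identical across scenarios, execution orders and run splits — the common
random numbers (CRN) construction.  The no-dementia counterfactual twin
reuses the same death threshold with the hazard ratio forced to 1 (and,
by default, the non-dementia HUI3 path), which makes per-actor scenario
orderings exact: years of life lost (YLL) is the twin's death age minus
the factual death age, health-adjusted YLL (HYLL) the difference in
HUI3-weighted years lived.

Within-year event order: emigration (January 1), onset draw (January 1,
onset date uniform within the year), death test, HUI3 assignment,
caregiving and cost accrual, then the end-of-year caregiving draw for the
following year.  Ages are in whole years as attained at January 1; the
age cap forces death at the 110th birthday.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .demography import ActorPopulation, EmptyPopulationError, build_actor_seeds
from .parameters import (
    AGE_MAX,
    HOUR_BINS,
    HUI3_MAX,
    HUI3_MIN,
    SECTORS,
    SEXES,
    ParameterSet,
)

# ---------------------------------------------------------------------------
# Counter-based random streams (CRN)
# ---------------------------------------------------------------------------

STREAM_DEATH = 1
STREAM_ONSET = 2
STREAM_ONSET_FRAC = 3
STREAM_HUI3 = 4
STREAM_CARE_RECEIPT = 5
STREAM_CARE_HOURS = 6
STREAM_EMIGRATION = 7

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLD = np.uint64(0x9E3779B97F4A7C15)


def _mix(z: np.ndarray) -> np.ndarray:
    """SplitMix64 finaliser (uint64 arrays, wrapping)."""
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


_MASK = (1 << 64) - 1


def _mix_int(z: int) -> int:
    """SplitMix64 finaliser on Python ints (no numpy scalar overflow)."""
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


@dataclass
class RandomStreams:
    """Per-actor independent substreams keyed by (seed, actor id, purpose, year).

    Counter-based: a draw is a pure hash of its coordinates, so the same
    actor id and master seed yield identical draws regardless of scenario,
    processing order, or how a run is split.
    """

    master_seed: int

    def __post_init__(self):
        if not 0 <= int(self.master_seed) < 2**63:
            raise ValueError("master seed must be a nonnegative 63-bit integer")
        self._key = np.uint64(_mix_int((int(self.master_seed) + 0x9E3779B97F4A7C15) & _MASK))

    def uniform(self, actor_ids, stream: int, counter: int = 0) -> np.ndarray:
        """Uniform(0, 1) draws, one per actor id (open at both ends)."""
        ids = np.asarray(actor_ids, dtype=np.uint64)
        off1 = np.uint64((int(stream) * 0x9E3779B97F4A7C15) & _MASK)
        off2 = np.uint64((int(counter) * 0x9E3779B97F4A7C15) & _MASK)
        z = _mix(self._key + ids * _GOLD)
        z = _mix(z + off1)
        z = _mix(z + off2)
        return ((z >> np.uint64(11)).astype(np.float64) + 0.5) * 2.0**-53

    def exponential(self, actor_ids, stream: int, counter: int = 0) -> np.ndarray:
        """Exponential(1) draws (inverse CDF of the uniforms)."""
        return -np.log1p(-self.uniform(actor_ids, stream, counter))

    def normal(self, actor_ids, stream: int, counter: int = 0) -> np.ndarray:
        """Standard normal draws (inverse CDF of the uniforms)."""
        return ndtri(self.uniform(actor_ids, stream, counter))


# ---------------------------------------------------------------------------
# Elementary operations (also used standalone in tests and docs)
# ---------------------------------------------------------------------------


def sample_death_age(hazard_path, threshold: float, cap: float = float(AGE_MAX)):
    """Invert the cumulative hazard of a piecewise-constant path exactly.

    ``hazard_path[k]`` is the hazard on age interval [k, k+1); the death
    age t* solves ``integral_0^t* h(u) du = threshold``.  If the
    cumulative hazard never reaches the threshold before ``cap``, death
    occurs at the cap.
    """
    h = np.asarray(hazard_path, dtype=float)
    if np.any(h < 0):
        raise ValueError("hazards must be nonnegative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cum = np.cumsum(h)
    k = int(np.searchsorted(cum, threshold))
    if k >= h.size:
        return min(float(h.size), cap)
    prev = cum[k - 1] if k > 0 else 0.0
    return min(k + (threshold - prev) / h[k], cap)


def rate_to_annual_prob(rate):
    # re-exported for convenience; canonical definition lives in parameters
    from .parameters import rate_to_annual_prob as _f

    return _f(rate)


def assign_dementia_onset(age: int, sex: int, year: int, params: ParameterSet,
                          streams: RandomStreams, actor_id: int):
    """January-1 onset draw for one dementia-free actor-year.

    Returns the continuous onset date (uniform within the year) or None.
    Below the declared minimum incidence age the probability is zero.
    """
    if age < params.metadata.incidence_min_age:
        return None
    rate = params.incidence.lookup(age, sex, year)
    p = -np.expm1(-rate)
    u = float(streams.uniform([actor_id], STREAM_ONSET, year)[0])
    if u < p:
        f = float(streams.uniform([actor_id], STREAM_ONSET_FRAC, year)[0])
        return year + f
    return None


def assign_caregiving(age: int, sex: int, dementia: bool, hui3: float,
                      params: ParameterSet, streams: RandomStreams,
                      actor_id: int, year: int) -> dict:
    """End-of-year caregiving draw for the following year.

    Receipt is Bernoulli on (age group, dementia status, HUI3 band);
    recipients get a weekly-hours bin, the caregiver's HUI3 and the
    caregiver's annual out-of-pocket expense.
    """
    cg = params.caregiving
    d = int(dementia)
    p = float(cg.receipt_prob[int(cg.group_index(age)), d, int(cg.band_index(hui3))])
    u = float(streams.uniform([actor_id], STREAM_CARE_RECEIPT, year)[0])
    if u >= p:
        return {"received": False, "bin": None, "weekly_hours": 0.0,
                "caregiver_hui3": None, "caregiver_oop": 0.0}
    uh = float(streams.uniform([actor_id], STREAM_CARE_HOURS, year)[0])
    b = int(np.searchsorted(cg.hours_cdf()[d], uh))
    b = min(b, len(HOUR_BINS) - 1)
    return {
        "received": True,
        "bin": HOUR_BINS[b],
        "weekly_hours": float(cg.hours_values[b]),
        "caregiver_hui3": float(cg.caregiver_hui3_mean),
        "caregiver_oop": float(cg.caregiver_oop),
    }


def compute_hyll(factual_hui3, factual_fractions, counterfactual_hui3,
                 counterfactual_fractions) -> float:
    """HYLL from two annual HUI3 paths with per-year fractions of year lived.

    HYLL = sum(counterfactual HUI3 x fraction lived)
         - sum(factual HUI3 x fraction lived); partial death years are
    prorated through the fractions.
    """
    f = np.asarray(factual_hui3, float) * np.asarray(factual_fractions, float)
    c = np.asarray(counterfactual_hui3, float) * np.asarray(counterfactual_fractions, float)
    return float(c.sum() - f.sum())


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

CARE_CATEGORIES = ("none",) + HOUR_BINS


@dataclass
class SimulationResult:
    """Population-level output of one run.

    Attributes
    ----------
    annual : DataFrame indexed by calendar year with weighted mid-year
        (July 1) population and dementia counts by sex and age stratum,
        event counts, caregiving volumes and bins, sector costs, and
        YLL/HYLL sums over that year's dementia decedents.
    events : per-year event log (raw actor counts and weighted) enabling
        exact accounting checks.
    actors : one row per actor (onset, death, counterfactual death,
        emigration, YLL, HYLL).
    strata : July-1 weighted population and dementia counts per
        (year, sex, 5-year age band from 40).
    """

    annual: pd.DataFrame
    events: pd.DataFrame
    actors: pd.DataFrame
    strata: pd.DataFrame
    weight: float
    n_actors: int
    seed: int
    scenario_name: str = "baseline"


@dataclass
class LifeCourse:
    """One actor's factual and counterfactual event history."""

    actor_id: int
    sex: str
    birth_time: float
    entry_year: int
    weight: float
    onset_date: float | None
    death_date: float | None
    counterfactual_death_date: float | None
    emigration_year: int | None
    yll: float
    hyll: float
    years: pd.DataFrame  # one row per simulated calendar year


# ---------------------------------------------------------------------------
# The vectorised year loop
# ---------------------------------------------------------------------------


def _band_edges_5y():
    # 40-44 ... 80-84, 85+ bands used for calibration strata
    return np.arange(40, 90, 5)


def _simulate(pop: ActorPopulation, params: ParameterSet, streams: RandomStreams,
              counterfactual_hui3: str = "nondementia", collector: list | None = None,
              force_onset_at_entry: bool = False):
    if counterfactual_hui3 not in ("nondementia", "factual_status"):
        raise ValueError("counterfactual_hui3 must be 'nondementia' or 'factual_status'")
    meta = params.metadata
    cg = params.caregiving
    cost = params.costs
    mig = params.demography.migration
    min_age = meta.incidence_min_age
    hours_cdf = cg.hours_cdf()

    # canonical storage order: ascending actor id (makes aggregates
    # independent of the order in which actors were supplied)
    pop = pop.permuted(np.argsort(pop.ids, kind="stable"))
    n = len(pop)
    ids = pop.ids
    sex = pop.sex.astype(np.int64)
    bt = pop.birth_time
    bfrac = bt - np.floor(bt)
    entry = pop.entry_year
    w = pop.weight

    E = streams.exponential(ids, STREAM_DEATH)

    entered = np.zeros(n, bool)
    emigrated = np.zeros(n, bool)
    emig_year = np.full(n, -1, np.int64)
    has_dem = np.zeros(n, bool)
    onset_time = np.full(n, np.nan)
    dead_f = np.zeros(n, bool)
    death_f = np.full(n, np.nan)
    death_year = np.full(n, -1, np.int64)
    dead_cf = np.zeros(n, bool)
    death_cf = np.full(n, np.nan)
    H_f = np.zeros(n)
    H_cf = np.zeros(n)
    hyll_f = np.zeros(n)
    hyll_cf = np.zeros(n)
    pending_care = np.zeros(n, bool)
    pending_bin = np.zeros(n, np.int64)

    y0 = int(entry[entry <= meta.year_end].min()) if np.any(entry <= meta.year_end) else meta.year_start
    y1 = meta.year_end
    years = np.arange(y0, y1 + 1)
    ny = years.size

    def zeros():
        return np.zeros(ny)

    agg = {k: zeros() for k in (
        "pop_mid", "pop_mid_m", "pop_mid_f",
        "pop40", "pop40_m", "pop40_f", "pop80", "pop80_m", "pop80_f",
        "pop_25_65",
        "dem_mid", "dem_mid_m", "dem_mid_f",
        "dem40", "dem40_m", "dem40_f", "dem80", "dem80_m", "dem80_f",
        "onsets_w", "deaths_w", "dem_deaths_w",
        "care_recipients_w", "care_hours_w", "caregiver_oop_w",
        "cost_oop_w", "yll_sum_w", "hyll_sum_w", "dem_decedents_w",
    )}
    for cat in CARE_CATEGORIES:
        agg[f"care_{cat}_w"] = zeros()
    for s in SECTORS:
        agg[f"cost_{s}_w"] = zeros()
    ev = {k: np.zeros(ny, np.int64) for k in (
        "entries_n", "emigrants_n", "dem_emigrants_n", "onsets_n",
        "deaths_n", "dem_deaths_n", "prev_jan_n", "pop_jan_n",
    )}

    bands5 = _band_edges_5y()
    strata_pop = np.zeros((ny, 2, bands5.size))
    strata_dem = np.zeros((ny, 2, bands5.size))

    t = y0
    t_stop = y1 + AGE_MAX + 2
    while t <= t_stop:
        reporting = t <= y1
        j = t - y0 if reporting else -1

        newly = entry == t
        if np.any(newly):
            entered |= newly
            if force_onset_at_entry:
                # study design for closed-form checks: dementia from entry
                has_dem |= newly
                onset_time[newly] = float(t)
            if reporting:
                ev["entries_n"][j] = int(newly.sum())
        active = entered & ~dead_f & ~emigrated
        active_cf = entered & ~dead_cf
        if not (active.any() or active_cf.any()):
            if not reporting:
                break
            t += 1
            continue

        age = np.floor(t - bt).astype(np.int64)

        if reporting:
            ev["prev_jan_n"][j] = int(np.count_nonzero(active & has_dem))
            ev["pop_jan_n"][j] = int(np.count_nonzero(active))

        # -- (1) emigration at January 1 ---------------------------------
        if reporting:
            em_mat = mig.emigration_year_matrix(t)
            ai = np.nonzero(active)[0]
            p_em = -np.expm1(-em_mat[sex[ai], np.minimum(age[ai], AGE_MAX)])
            out = streams.uniform(ids[ai], STREAM_EMIGRATION, t) < p_em
            if out.any():
                gone = ai[out]
                emigrated[gone] = True
                emig_year[gone] = t
                ev["emigrants_n"][j] = int(gone.size)
                ev["dem_emigrants_n"][j] = int(np.count_nonzero(has_dem[gone]))
                active = entered & ~dead_f & ~emigrated

        # -- (2) onset draw at January 1 ---------------------------------
        inc_mat = params.incidence.year_matrix(t)
        ei = np.nonzero(active & ~has_dem & (age >= min_age))[0]
        if ei.size:
            p_on = -np.expm1(-inc_mat[sex[ei], np.minimum(age[ei], AGE_MAX)])
            hit = streams.uniform(ids[ei], STREAM_ONSET, t) < p_on
            if hit.any():
                new = ei[hit]
                onset_time[new] = t + streams.uniform(ids[new], STREAM_ONSET_FRAC, t)
                has_dem[new] = True
                if reporting:
                    ev["onsets_n"][j] = int(new.size)
                    agg["onsets_w"][j] = w * new.size

        # -- (3) factual death test --------------------------------------
        m0_mat = params.mortality.year_matrix(t)
        hr_mat = params.hazard_ratio.year_matrix(t)
        ai = np.nonzero(active)[0]
        A = m0_mat[sex[ai], np.minimum(age[ai], AGE_MAX)]
        B = A * hr_mat[sex[ai], np.minimum(age[ai], AGE_MAX)]
        capv = np.where(age[ai] >= AGE_MAX - 1, bfrac[ai], 1.0)
        onset_now = has_dem[ai] & (onset_time[ai] >= t)
        f_on = np.where(onset_now, onset_time[ai] - t,
                        np.where(has_dem[ai], 0.0, capv))
        # when the effective HR is exactly 1 the split is arithmetic noise;
        # collapsing it keeps factual == counterfactual bit-for-bit
        f_on = np.where(B == A, capv, f_on)
        L1 = np.minimum(f_on, capv)
        L2 = capv - L1
        rem = E[ai] - H_f[ai]
        Hseg1 = A * L1
        cross1 = (Hseg1 >= rem) & (A > 0)
        rem2 = rem - Hseg1
        Hseg2 = B * L2
        cross2 = ~cross1 & (Hseg2 >= rem2) & (B > 0)
        frac_death = np.where(cross1, np.where(A > 0, rem / np.where(A > 0, A, 1.0), capv),
                              np.where(cross2, L1 + rem2 / np.where(B > 0, B, 1.0), capv))
        died = cross1 | cross2 | (age[ai] >= AGE_MAX - 1)
        frac_lived = np.where(died, frac_death, 1.0)
        dk = ai[died]
        dead_f[dk] = True
        death_f[dk] = t + frac_death[died]
        death_year[dk] = t
        H_f[ai[~died]] += (Hseg1 + Hseg2)[~died]
        if reporting and dk.size:
            ev["deaths_n"][j] = int(dk.size)
            ev["dem_deaths_n"][j] = int(np.count_nonzero(has_dem[dk]))
            agg["deaths_w"][j] = w * dk.size
            agg["dem_deaths_w"][j] = w * np.count_nonzero(has_dem[dk])

        # -- (4) counterfactual death test (HR == 1, no emigration) ------
        ci = np.nonzero(active_cf)[0]
        Ac = m0_mat[sex[ci], np.minimum(age[ci], AGE_MAX)]
        capc = np.where(age[ci] >= AGE_MAX - 1, bfrac[ci], 1.0)
        remc = E[ci] - H_cf[ci]
        Hc = Ac * capc
        crossc = (Hc >= remc) & (Ac > 0)
        frac_c = np.where(crossc, remc / np.where(Ac > 0, Ac, 1.0), capc)
        died_c = crossc | (age[ci] >= AGE_MAX - 1)
        frac_lived_c = np.where(died_c, frac_c, 1.0)
        dead_cf[ci[died_c]] = True
        death_cf[ci[died_c]] = t + frac_c[died_c]
        H_cf[ci[~died_c]] += Hc[~died_c]

        # -- (5) annual HUI3 and HYLL accrual ----------------------------
        un = np.nonzero(active | active_cf)[0]
        z_un = ndtri(streams.uniform(ids[un], STREAM_HUI3, t))
        z = np.full(n, np.nan)
        z[un] = z_un
        u_f = params.hui3.sample(np.minimum(age[ai], AGE_MAX), sex[ai],
                                 has_dem[ai].astype(int), z[ai])
        hyll_f[ai] += u_f * frac_lived
        if counterfactual_hui3 == "nondementia":
            dem_cf = np.zeros(ci.size, int)
        else:
            dem_cf = has_dem[ci].astype(int)
        u_cf = params.hui3.sample(np.minimum(age[ci], AGE_MAX), sex[ci], dem_cf, z[ci])
        hyll_cf[ci] += u_cf * frac_lived_c

        # full-population views of this year's factual exposure and HUI3
        u_f_full = np.full(n, np.nan)
        u_f_full[ai] = u_f
        lived_full = np.zeros(n)
        lived_full[ai] = frac_lived

        # -- (6) caregiving in force during year t (drawn at end of t-1) --
        care_now = np.zeros(n, bool)
        care_now[ai] = pending_care[ai]
        if reporting:
            rec = ai[pending_care[ai]]
            rec_dem = rec[has_dem[rec]]
            if rec_dem.size:
                hrs = cg.hours_values[pending_bin[rec_dem]] * 52.0 * lived_full[rec_dem]
                agg["care_hours_w"][j] = w * hrs.sum()
                agg["caregiver_oop_w"][j] = w * cg.caregiver_oop * lived_full[rec_dem].sum()

        # -- (7) cost accrual --------------------------------------------
        if reporting:
            di = ai[has_dem[ai]]
            if di.size:
                lived_end = t + lived_full[di]
                dem_start = np.maximum(float(t), onset_time[di])
                inc_frac = np.clip(np.minimum(onset_time[di] + 1.0, lived_end) - dem_start, 0.0, None)
                dem_frac = np.clip(lived_end - dem_start, 0.0, None)
                prev_frac = dem_frac - inc_frac
                grp = cost.group_index(np.minimum(age[di], AGE_MAX))
                c_inc = cost.annual_cost[:, 0, grp, sex[di]]
                c_prev = cost.annual_cost[:, 1, grp, sex[di]]
                sector_tot = w * (c_inc @ inc_frac + c_prev @ prev_frac)
                for k, s in enumerate(SECTORS):
                    agg[f"cost_{s}_w"][j] = sector_tot[k]
                agg["cost_oop_w"][j] = w * float(cost.out_of_pocket[grp, 1] @ dem_frac)

        # -- (8) July-1 point measures ------------------------------------
        if reporting:
            alive_mid = active & (~dead_f | (death_f > t + 0.5))
            age_mid = np.floor(t + 0.5 - bt).astype(np.int64)
            dem_mid = alive_mid & has_dem & (onset_time <= t + 0.5)
            male = sex == 0
            for name, mask in (("pop", alive_mid), ("dem", dem_mid)):
                a40 = mask & (age_mid >= 40)
                a80 = mask & (age_mid >= 80)
                if name == "pop":
                    agg["pop_mid"][j] = w * np.count_nonzero(mask)
                    agg["pop_mid_m"][j] = w * np.count_nonzero(mask & male)
                    agg["pop_mid_f"][j] = w * np.count_nonzero(mask & ~male)
                    agg["pop_25_65"][j] = w * np.count_nonzero(
                        mask & (age_mid >= 25) & (age_mid <= 65))
                else:
                    agg["dem_mid"][j] = w * np.count_nonzero(mask)
                    agg["dem_mid_m"][j] = w * np.count_nonzero(mask & male)
                    agg["dem_mid_f"][j] = w * np.count_nonzero(mask & ~male)
                agg[f"{name}40"][j] = w * np.count_nonzero(a40)
                agg[f"{name}40_m"][j] = w * np.count_nonzero(a40 & male)
                agg[f"{name}40_f"][j] = w * np.count_nonzero(a40 & ~male)
                agg[f"{name}80"][j] = w * np.count_nonzero(a80)
                agg[f"{name}80_m"][j] = w * np.count_nonzero(a80 & male)
                agg[f"{name}80_f"][j] = w * np.count_nonzero(a80 & ~male)
            # 5-year strata for calibration
            for smask, store in ((alive_mid, strata_pop), (dem_mid, strata_dem)):
                mi = np.nonzero(smask & (age_mid >= 40))[0]
                if mi.size:
                    b = np.minimum((age_mid[mi] - 40) // 5, bands5.size - 1)
                    for sx in (0, 1):
                        sel = sex[mi] == sx
                        store[j, sx] += w * np.bincount(b[sel], minlength=bands5.size)
            # caregiving recipients and bin percentages among July-1 demented
            dm = np.nonzero(dem_mid)[0]
            if dm.size:
                receiving = care_now[dm]
                agg["care_recipients_w"][j] = w * np.count_nonzero(receiving)
                agg["care_none_w"][j] = w * np.count_nonzero(~receiving)
                if receiving.any():
                    bc = np.bincount(pending_bin[dm[receiving]], minlength=len(HOUR_BINS))
                    for k, cat in enumerate(HOUR_BINS):
                        agg[f"care_{cat}_w"][j] = w * bc[k]

        # -- (9) end-of-year caregiving draw for year t+1 ------------------
        if reporting and t < y1:
            ae = ai[~dead_f[ai]]
            if ae.size:
                band = cg.band_index(u_f_full[ae])
                p_rec = cg.receipt_prob[cg.group_index(np.minimum(age[ae], AGE_MAX)),
                                        has_dem[ae].astype(int), band]
                got = streams.uniform(ids[ae], STREAM_CARE_RECEIPT, t) < p_rec
                uh = streams.uniform(ids[ae], STREAM_CARE_HOURS, t)
                cdf = hours_cdf[has_dem[ae].astype(int)]
                binv = np.minimum((uh[:, None] > cdf).sum(axis=1), len(HOUR_BINS) - 1)
                pending_care[ae] = got
                pending_bin[ae] = binv
                lost = ai[dead_f[ai]]
                pending_care[lost] = False

        if collector is not None:
            collector.append({
                "year": t,
                "active": active.copy(),
                "age": age.copy(),
                "dementia": has_dem.copy(),
                "hui3": u_f_full.copy(),
                "fraction_lived": lived_full.copy(),
                "care_received": care_now.copy(),
                "care_bin": pending_bin.copy(),
            })
        t += 1

    # ---- per-actor results ------------------------------------------------
    yll = np.where(dead_f & ~emigrated, death_cf - death_f, np.nan)
    hyll = np.where(dead_f & ~emigrated, hyll_cf - hyll_f, np.nan)

    # YLL / HYLL among each reporting year's dementia decedents
    dd = np.nonzero(dead_f & ~emigrated & has_dem & (death_year >= y0) & (death_year <= y1))[0]
    if dd.size:
        yj = death_year[dd] - y0
        agg["dem_decedents_w"] += w * np.bincount(yj, minlength=ny)
        agg["yll_sum_w"] += w * np.bincount(yj, weights=yll[dd], minlength=ny)
        agg["hyll_sum_w"] += w * np.bincount(yj, weights=hyll[dd], minlength=ny)

    for k in ("entries", "emigrants", "dem_emigrants", "onsets", "deaths",
              "dem_deaths", "prev_jan", "pop_jan"):
        ev[f"{k}_w"] = ev[f"{k}_n"] * w

    annual = pd.DataFrame({"year": years, **agg}).set_index("year")
    events = pd.DataFrame({"year": years, **ev}).set_index("year")
    actors = pd.DataFrame({
        "id": ids,
        "sex": np.array(SEXES)[sex],
        "birth_time": bt,
        "entry_year": entry,
        "onset_time": onset_time,
        "emig_year": np.where(emigrated, emig_year, -1),
        "death_time": death_f,
        "death_time_cf": death_cf,
        "yll": yll,
        "hyll": hyll,
    })
    rows = []
    for jj, y in enumerate(years):
        for sx in (0, 1):
            for bi, lo in enumerate(bands5):
                hi = lo + 4 if bi < bands5.size - 1 else None
                rows.append((y, SEXES[sx], f"{lo}-{hi}" if hi else f"{lo}+",
                             strata_pop[jj, sx, bi], strata_dem[jj, sx, bi]))
    strata = pd.DataFrame(rows, columns=["year", "sex", "age_band", "pop", "dem"])
    return annual, events, actors, strata


def run_population(params: ParameterSet, scenario=None, *, n_actors: int | None = None,
                   seed: int = 0, actors: ActorPopulation | None = None,
                   counterfactual_hui3: str = "nondementia",
                   force_onset_at_entry: bool = False) -> SimulationResult:
    """Simulate a weighted actor population and aggregate it per calendar year.

    Deterministic for a fixed master seed and bundle; the same seed gives
    every actor identical draws across scenarios (CRN).  Provide either
    ``n_actors`` (actors are sampled from the bundle's demography) or a
    pre-built ``actors`` population.
    """
    if scenario is not None:
        from .scenarios import apply_scenario

        params = apply_scenario(params, scenario)
        scen_name = scenario.name
    else:
        scen_name = "baseline"
    params.validate()
    if actors is None:
        if n_actors is None or n_actors <= 0:
            raise EmptyPopulationError("n_actors must be positive")
        actors = build_actor_seeds(
            params.demography.cohorts, params.demography.migration, n_actors, seed
        )
    streams = RandomStreams(seed)
    annual, events, adf, strata = _simulate(
        actors, params, streams, counterfactual_hui3=counterfactual_hui3,
        force_onset_at_entry=force_onset_at_entry,
    )
    return SimulationResult(
        annual=annual, events=events, actors=adf, strata=strata,
        weight=actors.weight, n_actors=len(actors), seed=seed,
        scenario_name=scen_name,
    )


def simulate_actor(seed_actor, params: ParameterSet, scenario=None,
                   streams: RandomStreams | None = None,
                   counterfactual_hui3: str = "nondementia",
                   force_onset_at_entry: bool = False) -> LifeCourse:
    """Simulate one actor's factual lifecourse and its counterfactual twin.

    Runs the same code path as :func:`run_population` on a single-actor
    population, so a lifecourse is guaranteed to agree with the
    population run that contains the same actor id and master seed.
    """
    if scenario is not None:
        from .scenarios import apply_scenario

        params = apply_scenario(params, scenario)
    if streams is None:
        streams = RandomStreams(0)
    pop = ActorPopulation(
        ids=np.array([seed_actor.id], np.int64),
        sex=np.array([seed_actor.sex if isinstance(seed_actor.sex, int)
                      else SEXES.index(seed_actor.sex)], np.int8),
        birth_time=np.array([seed_actor.birth_time]),
        entry_mode=np.array([0 if seed_actor.entry_mode == "born" else 1], np.int8),
        entry_year=np.array([seed_actor.entry_year], np.int64),
        weight=seed_actor.weight,
    )
    collected: list = []
    annual, events, adf, _ = _simulate(
        pop, params, streams, counterfactual_hui3=counterfactual_hui3,
        collector=collected, force_onset_at_entry=force_onset_at_entry,
    )
    row = adf.iloc[0]
    yrs = pd.DataFrame([
        {
            "year": rec["year"],
            "age": int(rec["age"][0]),
            "dementia": bool(rec["dementia"][0]),
            "hui3": float(rec["hui3"][0]),
            "fraction_lived": float(rec["fraction_lived"][0]),
            "care_received": bool(rec["care_received"][0]),
            "care_bin": HOUR_BINS[int(rec["care_bin"][0])] if rec["care_received"][0] else None,
        }
        for rec in collected if rec["active"][0]
    ])
    return LifeCourse(
        actor_id=int(row["id"]),
        sex=str(row["sex"]),
        birth_time=float(row["birth_time"]),
        entry_year=int(row["entry_year"]),
        weight=pop.weight,
        onset_date=None if np.isnan(row["onset_time"]) else float(row["onset_time"]),
        death_date=None if np.isnan(row["death_time"]) else float(row["death_time"]),
        counterfactual_death_date=(None if np.isnan(row["death_time_cf"])
                                   else float(row["death_time_cf"])),
        emigration_year=None if row["emig_year"] < 0 else int(row["emig_year"]),
        yll=float(row["yll"]) if not np.isnan(row["yll"]) else 0.0,
        hyll=float(row["hyll"]) if not np.isnan(row["hyll"]) else 0.0,
        years=yrs,
    )
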