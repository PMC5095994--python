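"""Rate tables and schedules that drive the dementia microsimulation.

A simulation is parameterised by one :class:`ParameterSet`: dementia
incidence hazards, baseline mortality with year-on-year improvement, the
dementia mortality hazard ratio, health-related quality of life (HUI3),
informal-caregiving probabilities and hours, sectoral health-care costs,
and the demographic schedules (birth cohorts, migration).

Tables live on a whole-year age grid 0..110 (the last row is open-ended:
lookups above the grid clamp to it) and a contiguous calendar-year span
(lookups outside the span clamp to the nearest endpoint).  No
interpolation is performed: rates are step functions in age and year.

Bundles are persisted as a directory of delimited text tables plus a YAML
manifest, and a seeded generator synthesises realistic bundles (Gompertz
mortality, exponentially rising late-life incidence, age-declining HUI3
with a dementia decrement) for desk-scale experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import CohortSchedule, MigrationSchedule

# ---------------------------------------------------------------------------
# Grid conventions
# ---------------------------------------------------------------------------

AGE_MAX = 110
N_AGES = AGE_MAX + 1
SEXES = ("male", "female")

HUI3_MIN = -0.36
HUI3_MAX = 1.0

SECTORS = (
    "physician",
    "hospitalization",
    "drug",
    "rehab",
    "assistive_devices",
    "home_care",
    "long_term_care",
)
PHASES = ("incident", "prevalent")

HOUR_BINS = ("lt7", "7to14", "15to70", "ge71")
#: Half-open weekly-hour bin edges [0,7), [7,15), [15,71), [71, inf).
HOUR_BIN_EDGES = (0.0, 7.0, 15.0, 71.0)

DEMENTIA_STATES = ("no", "yes")


class ParameterError(ValueError):
    """A parameter bundle violates one of its declared invariants."""


class MissingInputError(ParameterError):
    """A required table, column or category is absent from a bundle."""


class ConfigError(ValueError):
    """A synthesis or run configuration is inconsistent."""


def sex_index(sex) -> int:
    if isinstance(sex, str):
        try:
            return SEXES.index(sex)
        except ValueError:
            raise ParameterError(f"unknown sex {sex!r}; expected one of {SEXES}")
    s = int(sex)
    if s not in (0, 1):
        raise ParameterError(f"sex index must be 0 (male) or 1 (female), got {s}")
    return s


def age_group_labels(edges) -> list[str]:
    """Human-readable labels for age groups given their lower-bound edges."""
    edges = list(edges)
    labels = []
    for i, lo in enumerate(edges):
        if i + 1 < len(edges):
            labels.append(f"{lo}-{edges[i + 1] - 1}")
        else:
            labels.append(f"{lo}+")
    return labels


def age_group_index(edges, ages):
    """Map integer ages to age-group indices (edges are lower bounds)."""
    return np.searchsorted(np.asarray(edges)[1:], ages, side="right")


# ---------------------------------------------------------------------------
# AgeSexYearTable
# ---------------------------------------------------------------------------


@dataclass
class AgeSexYearTable:
    """A value per (age 0..110, sex, calendar year) with clamping lookups.

    Parameters
    ----------
    values
        Array of shape ``(111, 2, n_years)`` (age, sex, year).
    year_start
        First calendar year of the span; the span is contiguous.
    units
        Declared units (``"per person-year"``, ``"probability"``, ...).
    """

    values: np.ndarray
    year_start: int
    units: str = "per person-year"
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[:2] != (N_AGES, 2):
            raise ParameterError(
                f"table {self.name!r}: expected shape (111, 2, n_years), "
                f"got {self.values.shape}"
            )

    # -- span -------------------------------------------------------------
    @property
    def n_years(self) -> int:
        return self.values.shape[2]

    @property
    def year_end(self) -> int:
        return self.year_start + self.n_years - 1

    # -- construction ------------------------------------------------------
    @classmethod
    def from_constant(cls, value: float, year_start: int, year_end: int, **kw):
        n = year_end - year_start + 1
        return cls(np.full((N_AGES, 2, n), float(value)), year_start, **kw)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "AgeSexYearTable":
        """Build from a long table with columns age, sex, year, value."""
        for col in ("age", "sex", "year", "value"):
            if col not in df.columns:
                raise MissingInputError(f"missing input: column {col!r}")
        years = np.sort(df["year"].unique())
        y0, y1 = int(years[0]), int(years[-1])
        n = y1 - y0 + 1
        values = np.full((N_AGES, 2, n), np.nan)
        ai = df["age"].to_numpy(dtype=int)
        si = np.array([sex_index(s) for s in df["sex"]])
        yi = df["year"].to_numpy(dtype=int) - y0
        if ai.min() < 0 or ai.max() > AGE_MAX:
            raise ParameterError("age out of grid 0..110")
        values[ai, si, yi] = df["value"].to_numpy(dtype=float)
        tab = cls(values, y0, **kw)
        if np.isnan(values).any():
            a, s, y = [x[0] for x in np.nonzero(np.isnan(values))]
            raise MissingInputError(
                f"table {tab.name!r}: no value for "
                f"(age={a}, sex={SEXES[s]}, year={y0 + y})"
            )
        return tab

    def to_frame(self) -> pd.DataFrame:
        ages, sexes, years = np.meshgrid(
            np.arange(N_AGES),
            np.arange(2),
            np.arange(self.year_start, self.year_end + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "age": ages.ravel(),
                "sex": np.array(SEXES)[sexes.ravel()],
                "year": years.ravel(),
                "value": self.values.ravel(),
            }
        )

    # -- lookup ------------------------------------------------------------
    def _year_idx(self, year) -> np.ndarray:
        return np.clip(np.asarray(year, dtype=int) - self.year_start, 0, self.n_years - 1)

    def lookup(self, age, sex, year):
        """Cell value with age clamped above 110 and year clamped to the span.

        Negative ages are a domain error; no interpolation is performed.
        """
        age = np.asarray(age)
        if np.any(age < 0):
            raise ParameterError("age must be nonnegative")
        ai = np.minimum(age.astype(int), AGE_MAX)
        si = (
            np.array([sex_index(s) for s in np.atleast_1d(sex)]).reshape(np.shape(sex))
            if isinstance(sex, (list, np.ndarray))
            else sex_index(sex)
        )
        out = self.values[ai, si, self._year_idx(year)]
        return float(out) if np.isscalar(out) or out.ndim == 0 else out

    def year_matrix(self, year: int) -> np.ndarray:
        """Dense ``(2, 111)`` (sex, age) slice for one year, span-clamped."""
        return self.values[:, :, int(self._year_idx(year))].T

    # -- validation ---------------------------------------------------------
    def validate(self, kind: str = "hazard"):
        v = self.values
        bad = np.nonzero(v < 0)
        if bad[0].size:
            a, s, y = bad[0][0], bad[1][0], bad[2][0]
            raise ParameterError(
                f"table {self.name!r}: negative value {v[a, s, y]} at "
                f"(age={a}, sex={SEXES[s]}, year={self.year_start + y}); "
                f"rule: {kind} >= 0"
            )
        if kind == "probability" and np.any(v > 1):
            a, s, y = [x[0] for x in np.nonzero(v > 1)]
            raise ParameterError(
                f"table {self.name!r}: probability {v[a, s, y]} > 1 at "
                f"(age={a}, sex={SEXES[s]}, year={self.year_start + y})"
            )


def rate_lookup(table: AgeSexYearTable, age, sex, year):
    """Exact cell lookup with the clamping rules of :class:`AgeSexYearTable`."""
    return table.lookup(age, sex, year)


def rate_to_annual_prob(rate):
    """Convert a constant hazard (per person-year) to an annual event probability.

    ``p = 1 - exp(-rate)``; monotone in the rate and bounded in [0, 1).
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ParameterError("rate must be nonnegative")
    out = -np.expm1(-r)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Mortality with secular improvement
# ---------------------------------------------------------------------------

GROWTH_VARIANTS = ("low", "mid", "high")


@dataclass
class MortalityModel:
    """Baseline (all-cause, dementia-free) mortality with secular decline.

    The hazard at age ``a``, sex ``s`` and year ``t`` is

    ``m0(a, s, t) = reference(a, s) * exp(-rho(a, s) * k(variant) * (t - t_ref))``

    i.e. a per-age exponential improvement on a reference-year life table —
    the reduced form of a Lee-Carter style projection in which the time
    index declines linearly.  ``k`` is the life-expectancy growth-variant
    multiplier (low/mid/high).
    """

    reference_rates: np.ndarray  # (111, 2)
    reference_year: int
    improvement: np.ndarray  # (111, 2), rho >= 0 per year
    growth_variant: str = "mid"
    variant_multipliers: dict = field(
        default_factory=lambda: {"low": 0.5, "mid": 1.0, "high": 1.5}
    )

    def __post_init__(self):
        self.reference_rates = np.asarray(self.reference_rates, dtype=float)
        self.improvement = np.asarray(self.improvement, dtype=float)
        for arr, nm in ((self.reference_rates, "reference_rates"), (self.improvement, "improvement")):
            if arr.shape != (N_AGES, 2):
                raise ParameterError(f"mortality {nm}: expected shape (111, 2), got {arr.shape}")
        if np.any(self.reference_rates <= 0):
            raise ParameterError("mortality reference rates must be strictly positive")
        if np.any(self.improvement < 0):
            raise ParameterError("mortality improvement rates must be nonnegative")
        if self.growth_variant not in GROWTH_VARIANTS:
            raise ParameterError(f"growth_variant must be one of {GROWTH_VARIANTS}")

    @property
    def multiplier(self) -> float:
        return float(self.variant_multipliers[self.growth_variant])

    def rate(self, age, sex, year):
        age = np.asarray(age)
        if np.any(age < 0):
            raise ParameterError("age must be nonnegative")
        ai = np.minimum(age.astype(int), AGE_MAX)
        si = sex_index(sex) if not isinstance(sex, (list, np.ndarray)) else np.asarray(sex)
        dt = np.asarray(year, dtype=float) - self.reference_year
        out = self.reference_rates[ai, si] * np.exp(
            -self.improvement[ai, si] * self.multiplier * dt
        )
        return float(out) if out.ndim == 0 else out

    def year_matrix(self, year: int) -> np.ndarray:
        """(2, 111) baseline hazard slice for one calendar year."""
        dt = year - self.reference_year
        return (self.reference_rates * np.exp(-self.improvement * self.multiplier * dt)).T

    def with_variant(self, variant: str) -> "MortalityModel":
        return dataclasses.replace(self, growth_variant=variant)


# ---------------------------------------------------------------------------
# Hazard ratio, HUI3, caregiving, costs
# ---------------------------------------------------------------------------


@dataclass
class HazardRatioSpec:
    """Multiplicative excess mortality for persons with dementia."""

    hr: AgeSexYearTable
    scenario_multiplier: float = 1.0

    def __post_init__(self):
        if self.scenario_multiplier <= 0:
            raise ParameterError("hazard-ratio scenario multiplier must be positive")
        self.hr.validate("hazard")

    def year_matrix(self, year: int) -> np.ndarray:
        return self.hr.year_matrix(year) * self.scenario_multiplier

    def effective(self, age, sex, year):
        return self.hr.lookup(age, sex, year) * self.scenario_multiplier

    def scaled(self, multiplier: float) -> "HazardRatioSpec":
        return HazardRatioSpec(self.hr, self.scenario_multiplier * multiplier)


@dataclass
class HUI3Table:
    """Mean and dispersion of the Health Utilities Index Mark 3.

    HUI3 is a utility score on [-0.36, 1.0] (1 = perfect health, 0 = death,
    negative = states worse than death).  Cells are indexed by (age, sex,
    dementia status); an ``sd`` of 0 makes the cell deterministic, otherwise
    annual values are sampled from a normal around the mean and clipped to
    the HUI3 range.
    """

    mean: np.ndarray  # (111, 2, 2): age, sex, dementia (0 no, 1 yes)
    sd: np.ndarray  # same shape, >= 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        for arr, nm in ((self.mean, "mean"), (self.sd, "sd")):
            if arr.shape != (N_AGES, 2, 2):
                raise ParameterError(f"hui3 {nm}: expected shape (111, 2, 2), got {arr.shape}")
        if np.any(self.mean < HUI3_MIN) or np.any(self.mean > HUI3_MAX):
            raise ParameterError(f"hui3 means must lie in [{HUI3_MIN}, {HUI3_MAX}]")
        if np.any(self.sd < 0):
            raise ParameterError("hui3 sd must be nonnegative")

    def sample(self, age, sex_idx, dementia, z):
        """Mean + sd * z, clipped to the HUI3 range (vectorised)."""
        ai = np.minimum(np.asarray(age, dtype=int), AGE_MAX)
        mu = self.mean[ai, sex_idx, dementia]
        sd = self.sd[ai, sex_idx, dementia]
        return np.clip(mu + sd * z, HUI3_MIN, HUI3_MAX)


@dataclass
class CaregivingModel:
    """Receipt and intensity of informal (unpaid) care.

    Receipt is a Bernoulli event per person-year with probability indexed
    by (age group, dementia status, HUI3 band); recipients draw a weekly-
    hours bin from a categorical distribution (per dementia status) with a
    representative hours/week value per bin, and are assigned a caregiver
    HUI3 and annual caregiver out-of-pocket expense.
    """

    age_group_edges: tuple  # lower bounds, e.g. (0, 65, 75, 85)
    hui3_band_edges: tuple  # interior lower bounds incl. floor, e.g. (-0.36, 0.4, 0.7)
    receipt_prob: np.ndarray  # (n_groups, 2 dementia, n_bands)
    hours_probs: np.ndarray  # (2 dementia, 4 bins)
    hours_values: np.ndarray  # (4,) representative weekly hours per bin
    caregiver_hui3_mean: float
    caregiver_oop: float

    def __post_init__(self):
        self.age_group_edges = tuple(int(e) for e in self.age_group_edges)
        self.hui3_band_edges = tuple(float(e) for e in self.hui3_band_edges)
        self.receipt_prob = np.asarray(self.receipt_prob, dtype=float)
        self.hours_probs = np.asarray(self.hours_probs, dtype=float)
        self.hours_values = np.asarray(self.hours_values, dtype=float)
        ng, nb = len(self.age_group_edges), len(self.hui3_band_edges)
        if self.receipt_prob.shape != (ng, 2, nb):
            raise ParameterError(
                f"caregiving receipt_prob: expected shape ({ng}, 2, {nb}), "
                f"got {self.receipt_prob.shape}"
            )
        if np.any(self.receipt_prob < 0) or np.any(self.receipt_prob > 1):
            raise ParameterError("caregiving receipt probabilities must lie in [0, 1]")
        if self.hours_probs.shape != (2, len(HOUR_BINS)):
            raise ParameterError("caregiving hours_probs: expected shape (2, 4)")
        if np.any(self.hours_probs < 0):
            raise ParameterError("caregiving hours probabilities must be nonnegative")
        sums = self.hours_probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ParameterError(
                f"caregiving hours probabilities must sum to 1 per dementia status "
                f"(got {sums.tolist()})"
            )
        lo = np.array(HOUR_BIN_EDGES)
        hi = np.append(lo[1:], np.inf)
        if np.any(self.hours_values < lo) or np.any(self.hours_values >= hi):
            raise ParameterError("representative weekly hours must fall inside their bin")
        if not (HUI3_MIN <= self.caregiver_hui3_mean <= HUI3_MAX):
            raise ParameterError("caregiver HUI3 mean must lie in the HUI3 range")
        if self.caregiver_oop < 0:
            raise ParameterError("caregiver out-of-pocket must be nonnegative")

    def group_index(self, ages):
        return age_group_index(self.age_group_edges, ages)

    def band_index(self, hui3):
        return np.searchsorted(np.asarray(self.hui3_band_edges)[1:], hui3, side="right")

    def receipt_probability(self, ages, dementia, hui3):
        return self.receipt_prob[self.group_index(ages), dementia, self.band_index(hui3)]

    def hours_cdf(self) -> np.ndarray:
        return np.cumsum(self.hours_probs, axis=1)


@dataclass
class CostSchedule:
    """Annual formal health-care costs by sector and disease phase.

    ``annual_cost[sector, phase, age group, sex]`` applies while a person
    lives with dementia; the *incident* phase is the 12 months following
    onset, *prevalent* thereafter.  Out-of-pocket expenses are indexed by
    (age group, dementia status) and reported separately from the seven
    formal sectors.
    """

    age_group_edges: tuple
    annual_cost: np.ndarray  # (7 sectors, 2 phases, n_groups, 2 sexes)
    out_of_pocket: np.ndarray  # (n_groups, 2 dementia)

    def __post_init__(self):
        self.age_group_edges = tuple(int(e) for e in self.age_group_edges)
        self.annual_cost = np.asarray(self.annual_cost, dtype=float)
        self.out_of_pocket = np.asarray(self.out_of_pocket, dtype=float)
        ng = len(self.age_group_edges)
        if self.annual_cost.shape != (len(SECTORS), len(PHASES), ng, 2):
            raise ParameterError(
                f"cost schedule: expected shape ({len(SECTORS)}, 2, {ng}, 2), "
                f"got {self.annual_cost.shape}"
            )
        if self.out_of_pocket.shape != (ng, 2):
            raise ParameterError(f"out-of-pocket: expected shape ({ng}, 2)")
        if np.any(self.annual_cost < 0) or np.any(self.out_of_pocket < 0):
            raise ParameterError("costs must be nonnegative")

    def group_index(self, ages):
        return age_group_index(self.age_group_edges, ages)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------


@dataclass
class Demography:
    cohorts: CohortSchedule
    migration: MigrationSchedule


@dataclass
class Metadata:
    name: str
    year_start: int
    year_end: int
    currency_year: int
    incidence_min_age: int


@dataclass
class ParameterSet:
    """The complete input bundle for one simulation run."""

    incidence: AgeSexYearTable
    mortality: MortalityModel
    hazard_ratio: HazardRatioSpec
    hui3: HUI3Table
    caregiving: CaregivingModel
    costs: CostSchedule
    demography: Demography
    metadata: Metadata

    def validate(self) -> "ParameterSet":
        m = self.metadata
        self.incidence.validate("hazard")
        for tab, nm in ((self.incidence, "incidence"), (self.hazard_ratio.hr, "hazard_ratio")):
            if tab.year_start > m.year_start or tab.year_end < m.year_end:
                raise ParameterError(
                    f"table {nm}: year span {tab.year_start}-{tab.year_end} does not "
                    f"cover the horizon {m.year_start}-{m.year_end}"
                )
        below = self.incidence.values[: m.incidence_min_age]
        if np.any(below != 0):
            a, s, y = [x[0] for x in np.nonzero(below)]
            raise ParameterError(
                f"incidence must be 0 below age {m.incidence_min_age}; "
                f"found {below[a, s, y]} at (age={a}, sex={SEXES[s]}, "
                f"year={self.incidence.year_start + y})"
            )
        return self

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = (
    "incidence",
    "mortality_reference",
    "mortality_improvement",
    "hazard_ratio",
    "hui3",
    "caregiving_receipt",
    "caregiving_hours",
    "costs",
    "out_of_pocket",
    "cohorts",
    "immigration",
    "emigration",
)


def save_parameter_set(params: ParameterSet, path) -> Path:
    """Write a bundle directory: ``manifest.yaml`` plus one CSV per table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = params.metadata
    mort = params.mortality
    cg = params.caregiving
    manifest = {
        "name": m.name,
        "year_start": m.year_start,
        "year_end": m.year_end,
        "currency_year": m.currency_year,
        "incidence_min_age": m.incidence_min_age,
        "mortality": {
            "reference_year": mort.reference_year,
            "growth_variant": mort.growth_variant,
            "variant_multipliers": {k: float(v) for k, v in mort.variant_multipliers.items()},
        },
        "hazard_ratio": {"scenario_multiplier": float(params.hazard_ratio.scenario_multiplier)},
        "caregiving": {
            "age_group_edges": list(cg.age_group_edges),
            "hui3_band_edges": [float(e) for e in cg.hui3_band_edges],
            "caregiver_hui3_mean": float(cg.caregiver_hui3_mean),
            "caregiver_oop": float(cg.caregiver_oop),
        },
        "costs": {"age_group_edges": list(params.costs.age_group_edges)},
        "migration": {
            "arrival_age_group_edges": list(params.demography.migration.arrival_age_group_edges),
            "emigration_age_group_edges": list(params.demography.migration.emigration_age_group_edges),
        },
        "tables": {t: f"{t}.csv" for t in _TABLE_FILES},
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    def w(name, df):
        df.to_csv(path / manifest["tables"][name], index=False)

    w("incidence", params.incidence.to_frame())
    w("hazard_ratio", params.hazard_ratio.hr.to_frame())
    ages = np.repeat(np.arange(N_AGES), 2)
    sexes = np.tile(np.array(SEXES), N_AGES)
    w(
        "mortality_reference",
        pd.DataFrame({"age": ages, "sex": sexes, "value": mort.reference_rates.ravel()}),
    )
    w(
        "mortality_improvement",
        pd.DataFrame({"age": ages, "sex": sexes, "value": mort.improvement.ravel()}),
    )
    ad, sd_, dd = np.meshgrid(np.arange(N_AGES), np.arange(2), np.arange(2), indexing="ij")
    w(
        "hui3",
        pd.DataFrame(
            {
                "age": ad.ravel(),
                "sex": np.array(SEXES)[sd_.ravel()],
                "dementia": np.array(DEMENTIA_STATES)[dd.ravel()],
                "mean": params.hui3.mean.ravel(),
                "sd": params.hui3.sd.ravel(),
            }
        ),
    )
    glabels = age_group_labels(cg.age_group_edges)
    gi, di, bi = np.meshgrid(
        np.arange(len(glabels)), np.arange(2), np.arange(len(cg.hui3_band_edges)), indexing="ij"
    )
    w(
        "caregiving_receipt",
        pd.DataFrame(
            {
                "age_group": np.array(glabels)[gi.ravel()],
                "dementia": np.array(DEMENTIA_STATES)[di.ravel()],
                "hui3_band": bi.ravel(),
                "value": cg.receipt_prob.ravel(),
            }
        ),
    )
    di, bi = np.meshgrid(np.arange(2), np.arange(len(HOUR_BINS)), indexing="ij")
    w(
        "caregiving_hours",
        pd.DataFrame(
            {
                "dementia": np.array(DEMENTIA_STATES)[di.ravel()],
                "bin": np.array(HOUR_BINS)[bi.ravel()],
                "prob": cg.hours_probs.ravel(),
                "hours": np.tile(cg.hours_values, 2),
            }
        ),
    )
    clabels = age_group_labels(params.costs.age_group_edges)
    si, pi, gi, xi = np.meshgrid(
        np.arange(len(SECTORS)), np.arange(2), np.arange(len(clabels)), np.arange(2), indexing="ij"
    )
    w(
        "costs",
        pd.DataFrame(
            {
                "sector": np.array(SECTORS)[si.ravel()],
                "phase": np.array(PHASES)[pi.ravel()],
                "age_group": np.array(clabels)[gi.ravel()],
                "sex": np.array(SEXES)[xi.ravel()],
                "value": params.costs.annual_cost.ravel(),
            }
        ),
    )
    gi, di = np.meshgrid(np.arange(len(clabels)), np.arange(2), indexing="ij")
    w(
        "out_of_pocket",
        pd.DataFrame(
            {
                "age_group": np.array(clabels)[gi.ravel()],
                "dementia": np.array(DEMENTIA_STATES)[di.ravel()],
                "value": params.costs.out_of_pocket.ravel(),
            }
        ),
    )
    w("cohorts", params.demography.cohorts.to_frame())
    imm, emi = params.demography.migration.to_frames()
    w("immigration", imm)
    w("emigration", emi)
    return path


def load_parameter_set(path) -> ParameterSet:
    """Read and validate a bundle directory written by :func:`save_parameter_set`."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise MissingInputError(f"missing input: manifest.yaml in {path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    tables = manifest.get("tables", {})

    def read(name) -> pd.DataFrame:
        if name not in tables:
            raise MissingInputError(f"missing input: {name}")
        f = path / tables[name]
        if not f.exists():
            raise MissingInputError(f"missing input: {name} ({f.name})")
        # round_trip: bit-exact save/load of every table cell
        return pd.read_csv(f, float_precision="round_trip")

    def pivot_age_sex(df, name) -> np.ndarray:
        out = np.full((N_AGES, 2), np.nan)
        out[df["age"].to_numpy(int), [sex_index(s) for s in df["sex"]]] = df["value"].to_numpy(float)
        if np.isnan(out).any():
            a, s = [x[0] for x in np.nonzero(np.isnan(out))]
            raise MissingInputError(f"missing input: {name} cell (age={a}, sex={SEXES[s]})")
        return out

    incidence = AgeSexYearTable.from_frame(read("incidence"), name="incidence")
    hr_tab = AgeSexYearTable.from_frame(read("hazard_ratio"), units="ratio", name="hazard_ratio")
    mort_cfg = manifest["mortality"]
    mortality = MortalityModel(
        reference_rates=pivot_age_sex(read("mortality_reference"), "mortality_reference"),
        reference_year=int(mort_cfg["reference_year"]),
        improvement=pivot_age_sex(read("mortality_improvement"), "mortality_improvement"),
        growth_variant=mort_cfg.get("growth_variant", "mid"),
        variant_multipliers=mort_cfg.get(
            "variant_multipliers", {"low": 0.5, "mid": 1.0, "high": 1.5}
        ),
    )
    hdf = read("hui3")
    mean = np.full((N_AGES, 2, 2), np.nan)
    sd = np.full((N_AGES, 2, 2), np.nan)
    di = [DEMENTIA_STATES.index(d) for d in hdf["dementia"]]
    mean[hdf["age"].to_numpy(int), [sex_index(s) for s in hdf["sex"]], di] = hdf["mean"]
    sd[hdf["age"].to_numpy(int), [sex_index(s) for s in hdf["sex"]], di] = hdf["sd"]
    if np.isnan(mean).any() or np.isnan(sd).any():
        raise MissingInputError("missing input: hui3 cell")
    hui3 = HUI3Table(mean, sd)

    cg_cfg = manifest["caregiving"]
    edges = tuple(cg_cfg["age_group_edges"])
    bands = tuple(cg_cfg["hui3_band_edges"])
    glabels = age_group_labels(edges)
    rdf = read("caregiving_receipt")
    receipt = np.full((len(edges), 2, len(bands)), np.nan)
    receipt[
        [glabels.index(g) for g in rdf["age_group"]],
        [DEMENTIA_STATES.index(d) for d in rdf["dementia"]],
        rdf["hui3_band"].to_numpy(int),
    ] = rdf["value"]
    if np.isnan(receipt).any():
        raise MissingInputError("missing input: caregiving_receipt cell")
    hdf2 = read("caregiving_hours")
    hprobs = np.full((2, len(HOUR_BINS)), np.nan)
    hvals = np.full(len(HOUR_BINS), np.nan)
    for _, row in hdf2.iterrows():
        b = HOUR_BINS.index(row["bin"])
        hprobs[DEMENTIA_STATES.index(row["dementia"]), b] = row["prob"]
        hvals[b] = row["hours"]
    if np.isnan(hprobs).any() or np.isnan(hvals).any():
        raise MissingInputError("missing input: caregiving_hours cell")
    caregiving = CaregivingModel(
        age_group_edges=edges,
        hui3_band_edges=bands,
        receipt_prob=receipt,
        hours_probs=hprobs,
        hours_values=hvals,
        caregiver_hui3_mean=float(cg_cfg["caregiver_hui3_mean"]),
        caregiver_oop=float(cg_cfg["caregiver_oop"]),
    )

    cedges = tuple(manifest["costs"]["age_group_edges"])
    clabels = age_group_labels(cedges)
    cdf = read("costs")
    missing_sectors = set(SECTORS) - set(cdf["sector"])
    if missing_sectors:
        raise MissingInputError(f"missing input: {sorted(missing_sectors)[0]}")
    cost_arr = np.full((len(SECTORS), 2, len(cedges), 2), np.nan)
    cost_arr[
        [SECTORS.index(s) for s in cdf["sector"]],
        [PHASES.index(p) for p in cdf["phase"]],
        [clabels.index(g) for g in cdf["age_group"]],
        [sex_index(s) for s in cdf["sex"]],
    ] = cdf["value"]
    if np.isnan(cost_arr).any():
        raise MissingInputError("missing input: costs cell")
    odf = read("out_of_pocket")
    oop = np.full((len(cedges), 2), np.nan)
    oop[
        [clabels.index(g) for g in odf["age_group"]],
        [DEMENTIA_STATES.index(d) for d in odf["dementia"]],
    ] = odf["value"]
    if np.isnan(oop).any():
        raise MissingInputError("missing input: out_of_pocket cell")
    costs = CostSchedule(cedges, cost_arr, oop)

    mig_cfg = manifest["migration"]
    cohorts = CohortSchedule.from_frame(read("cohorts"))
    migration = MigrationSchedule.from_frames(
        read("immigration"),
        read("emigration"),
        arrival_age_group_edges=tuple(mig_cfg["arrival_age_group_edges"]),
        emigration_age_group_edges=tuple(mig_cfg["emigration_age_group_edges"]),
    )

    params = ParameterSet(
        incidence=incidence,
        mortality=mortality,
        hazard_ratio=HazardRatioSpec(hr_tab, float(manifest["hazard_ratio"]["scenario_multiplier"])),
        hui3=hui3,
        caregiving=caregiving,
        costs=costs,
        demography=Demography(cohorts, migration),
        metadata=Metadata(
            name=manifest["name"],
            year_start=int(manifest["year_start"]),
            year_end=int(manifest["year_end"]),
            currency_year=int(manifest["currency_year"]),
            incidence_min_age=int(manifest["incidence_min_age"]),
        ),
    )
    return params.validate()


# ---------------------------------------------------------------------------
# Synthetic parameter bundles
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Shape parameters for the synthetic bundle generator.

    Defaults emulate a developed-country setting on a desk-scale span:
    Gompertz adult mortality with ~1 %/yr secular improvement, dementia
    incidence doubling roughly every 5.5 years of age from late midlife,
    a constant dementia mortality hazard ratio of 2, HUI3 declining
    gently with age with a large dementia decrement, 77 % informal-care
    receipt among persons with dementia, and sector costs dominated by
    long-term care and hospitalization.
    """

    name: str = "synthetic"
    year_start: int = 1950
    year_end: int = 2040
    #: birth cohorts reach further back than the rate tables so that the
    #: horizon has a full age pyramid; lookups before the table span clamp
    cohort_year_start: int = 1900
    reference_year: int = 2006
    currency_year: int = 2011

    # mortality: m(a) = alpha * exp(beta * a), capped
    gompertz_alpha: float = 3.5e-5
    gompertz_beta: float = 0.092
    mortality_cap: float = 0.95
    male_mortality_factor: float = 1.35
    improvement_rate: float = 0.01  # rho, log-decline per calendar year
    variant_multipliers: tuple = (0.5, 1.0, 1.5)  # low, mid, high

    # incidence: i(a) = i65 * 2**((a - 65)/doubling), 0 below min age, capped
    incidence_min_age: int = 40
    incidence_rate_at_65: float = 0.004
    incidence_doubling_time: float = 5.5
    incidence_cap: float = 0.35
    female_incidence_factor: float = 1.05

    # hazard ratio (constant across cells by default)
    hazard_ratio: float = 2.0

    # HUI3: mean(a) = base - slope*max(0, a-20), minus a dementia decrement
    hui3_base: float = 0.95
    hui3_age_slope: float = 0.0022
    dementia_hui3_decrement: float = 0.35
    hui3_sd: float = 0.05

    # caregiving
    caregiving_age_group_edges: tuple = (0, 65, 75, 85)
    hui3_band_edges: tuple = (-0.36, 0.4, 0.7)
    receipt_prob_dementia: float = 0.77
    receipt_prob_nondementia: float = 0.04
    hours_probs_dementia: tuple = (0.001, 0.002, 0.345, 0.652)
    hours_probs_nondementia: tuple = (0.40, 0.30, 0.25, 0.05)
    hours_values: tuple = (3.5, 10.5, 40.0, 80.0)
    caregiver_hui3_mean: float = 0.85
    caregiver_oop: float = 1000.0

    # costs (currency/year while living with dementia), prevalent phase
    cost_age_group_edges: tuple = (0, 65, 75, 85)
    sector_costs: tuple = (2100.0, 7300.0, 2900.0, 250.0, 235.0, 1700.0, 12400.0)
    incident_multipliers: tuple = (1.5, 1.5, 1.5, 1.0, 1.0, 1.0, 1.0)
    oop_dementia: float = 1500.0
    oop_nondementia: float = 300.0

    # demography
    births_per_year_per_sex: float = 190_000.0
    immigration_per_year: float = 120_000.0
    arrival_age_group_edges: tuple = (0, 20, 40, 65)
    arrival_age_props: tuple = (0.30, 0.45, 0.20, 0.05)
    emigration_rate: float = 0.002

    # seed-driven level jitter (multiplicative, per sex) on incidence/mortality
    jitter_sd: float = 0.02


def synthesize_parameter_set(seed: int, config: SynthConfig | None = None) -> ParameterSet:
    """Generate a validated synthetic :class:`ParameterSet`.

    Deterministic for identical ``(seed, config)``.  The seed drives mild
    per-sex level jitter on mortality and incidence so distinct seeds give
    distinct (but structurally identical) worlds; curve shapes and the
    caregiving/cost levels come from the config alone.
    """
    cfg = config or SynthConfig()
    if cfg.gompertz_beta <= 0:
        raise ConfigError("Gompertz beta must be positive")
    if cfg.incidence_doubling_time <= 0:
        raise ConfigError("incidence doubling time must be positive")
    rng = np.random.default_rng(seed)
    jit = np.exp(rng.normal(0.0, cfg.jitter_sd, size=4)) if cfg.jitter_sd > 0 else np.ones(4)
    mort_jit, inc_jit = jit[:2], jit[2:]

    years = np.arange(cfg.year_start, cfg.year_end + 1)
    ages = np.arange(N_AGES, dtype=float)

    # mortality reference: Gompertz per sex, capped
    base = cfg.gompertz_alpha * np.exp(cfg.gompertz_beta * ages)
    ref = np.empty((N_AGES, 2))
    ref[:, 0] = np.minimum(base * cfg.male_mortality_factor * mort_jit[0], cfg.mortality_cap)
    ref[:, 1] = np.minimum(base * mort_jit[1], cfg.mortality_cap)
    mortality = MortalityModel(
        reference_rates=ref,
        reference_year=cfg.reference_year,
        improvement=np.full((N_AGES, 2), cfg.improvement_rate),
        growth_variant="mid",
        variant_multipliers=dict(zip(GROWTH_VARIANTS, cfg.variant_multipliers)),
    )

    # incidence: exponential in age above the minimum age, constant in year
    inc_curve = cfg.incidence_rate_at_65 * 2.0 ** ((ages - 65.0) / cfg.incidence_doubling_time)
    inc_curve = np.minimum(inc_curve, cfg.incidence_cap)
    inc_curve[: cfg.incidence_min_age] = 0.0
    inc = np.empty((N_AGES, 2))
    inc[:, 0] = np.minimum(inc_curve * inc_jit[0], cfg.incidence_cap)
    inc[:, 1] = np.minimum(inc_curve * cfg.female_incidence_factor * inc_jit[1], cfg.incidence_cap)
    incidence = AgeSexYearTable(
        np.repeat(inc[:, :, None], len(years), axis=2), cfg.year_start, name="incidence"
    )

    hr_tab = AgeSexYearTable.from_constant(
        cfg.hazard_ratio, cfg.year_start, cfg.year_end, units="ratio", name="hazard_ratio"
    )

    # HUI3: gentle age decline, dementia decrement, clipped to range
    nodem = np.clip(cfg.hui3_base - cfg.hui3_age_slope * np.maximum(ages - 20.0, 0.0), HUI3_MIN, HUI3_MAX)
    dem = np.clip(nodem - cfg.dementia_hui3_decrement, HUI3_MIN, HUI3_MAX)
    mean = np.stack(
        [np.stack([nodem, dem], axis=1), np.stack([nodem, dem], axis=1)], axis=1
    )
    hui3 = HUI3Table(mean, np.full((N_AGES, 2, 2), cfg.hui3_sd))

    ng, nb = len(cfg.caregiving_age_group_edges), len(cfg.hui3_band_edges)
    receipt = np.empty((ng, 2, nb))
    receipt[:, 0, :] = cfg.receipt_prob_nondementia
    receipt[:, 1, :] = cfg.receipt_prob_dementia
    caregiving = CaregivingModel(
        age_group_edges=cfg.caregiving_age_group_edges,
        hui3_band_edges=cfg.hui3_band_edges,
        receipt_prob=receipt,
        hours_probs=np.array([cfg.hours_probs_nondementia, cfg.hours_probs_dementia]),
        hours_values=np.array(cfg.hours_values),
        caregiver_hui3_mean=cfg.caregiver_hui3_mean,
        caregiver_oop=cfg.caregiver_oop,
    )

    ngc = len(cfg.cost_age_group_edges)
    cost = np.empty((len(SECTORS), 2, ngc, 2))
    for k in range(len(SECTORS)):
        cost[k, 1, :, :] = cfg.sector_costs[k]
        cost[k, 0, :, :] = cfg.sector_costs[k] * cfg.incident_multipliers[k]
    oop = np.empty((ngc, 2))
    oop[:, 0] = cfg.oop_nondementia
    oop[:, 1] = cfg.oop_dementia
    costs = CostSchedule(cfg.cost_age_group_edges, cost, oop)

    cohorts = CohortSchedule.constant(
        cfg.cohort_year_start, cfg.year_end, cfg.births_per_year_per_sex
    )
    migration = MigrationSchedule.constant(
        cfg.year_start,
        cfg.year_end,
        immigration_per_year=cfg.immigration_per_year,
        arrival_age_group_edges=cfg.arrival_age_group_edges,
        arrival_age_props=cfg.arrival_age_props,
        emigration_rate=cfg.emigration_rate,
    )

    params = ParameterSet(
        incidence=incidence,
        mortality=mortality,
        hazard_ratio=HazardRatioSpec(hr_tab),
        hui3=hui3,
        caregiving=caregiving,
        costs=costs,
        demography=Demography(cohorts, migration),
        metadata=Metadata(
            name=cfg.name,
            year_start=cfg.year_start,
            year_end=cfg.year_end,
            currency_year=cfg.currency_year,
            incidence_min_age=cfg.incidence_min_age,
        ),
    )
    return params.validate()


def constant_rate_parameter_set(
    *,
    mortality_rate: float,
    hazard_ratio: float = 1.0,
    incidence_rate: float = 0.0,
    incidence_min_age: int = 0,
    hui3_nodem: float = 0.8,
    hui3_dem: float = 0.8,
    hui3_sd: float = 0.0,
    receipt_dementia: float = 0.0,
    receipt_nondementia: float = 0.0,
    hours_probs: tuple = (0.25, 0.25, 0.25, 0.25),
    sector_cost: float = 0.0,
    incident_cost: float | None = None,
    oop_dementia: float = 0.0,
    year_start: int = 2000,
    year_end: int = 2002,
    births_per_year_per_sex: float = 1000.0,
    cohort_years: int | None = None,
    emigration_rate: float = 0.0,
) -> ParameterSet:
    """A bundle with age-, sex- and year-constant rates, for controlled
    experiments where closed forms exist (constant-hazard survival,
    binomial caregiving receipt, phase-prorated costs).

    No immigration; births run over ``cohort_years`` years from
    ``year_start`` (default: the whole span).
    """
    if mortality_rate <= 0:
        raise ConfigError("mortality_rate must be strictly positive")
    inc = np.full((N_AGES, 2), float(incidence_rate))
    inc[:incidence_min_age] = 0.0
    n_years = year_end - year_start + 1
    incidence = AgeSexYearTable(
        np.repeat(inc[:, :, None], n_years, axis=2), year_start, name="incidence"
    )
    mortality = MortalityModel(
        reference_rates=np.full((N_AGES, 2), float(mortality_rate)),
        reference_year=year_start,
        improvement=np.zeros((N_AGES, 2)),
    )
    hr_tab = AgeSexYearTable.from_constant(
        hazard_ratio, year_start, year_end, units="ratio", name="hazard_ratio"
    )
    mean = np.empty((N_AGES, 2, 2))
    mean[:, :, 0] = hui3_nodem
    mean[:, :, 1] = hui3_dem
    hui3 = HUI3Table(mean, np.full((N_AGES, 2, 2), float(hui3_sd)))
    receipt = np.empty((1, 2, 1))
    receipt[:, 0, :] = receipt_nondementia
    receipt[:, 1, :] = receipt_dementia
    caregiving = CaregivingModel(
        age_group_edges=(0,),
        hui3_band_edges=(HUI3_MIN,),
        receipt_prob=receipt,
        hours_probs=np.tile(np.asarray(hours_probs, float), (2, 1)),
        hours_values=np.array([3.5, 10.5, 40.0, 80.0]),
        caregiver_hui3_mean=0.85,
        caregiver_oop=0.0,
    )
    if incident_cost is None:
        incident_cost = sector_cost
    cost = np.empty((len(SECTORS), 2, 1, 2))
    cost[:, 0] = float(incident_cost)
    cost[:, 1] = float(sector_cost)
    oop = np.array([[0.0, float(oop_dementia)]])
    costs = CostSchedule((0,), cost, oop)
    if cohort_years is None:
        cohort_years = n_years
    cohorts = CohortSchedule.constant(
        year_start, year_start + cohort_years - 1, births_per_year_per_sex
    )
    migration = MigrationSchedule.constant(
        year_start, year_end, immigration_per_year=0.0, emigration_rate=emigration_rate
    )
    params = ParameterSet(
        incidence=incidence,
        mortality=mortality,
        hazard_ratio=HazardRatioSpec(hr_tab),
        hui3=hui3,
        caregiving=caregiving,
        costs=costs,
        demography=Demography(cohorts, migration),
        metadata=Metadata(
            name="constant-rate",
            year_start=year_start,
            year_end=year_end,
            currency_year=year_start,
            incidence_min_age=incidence_min_age,
        ),
    )
    return params.validate()
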