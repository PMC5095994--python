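"""Open synthetic population: birth cohorts, immigration and emigration.

The simulated population is *open*: actors enter either at birth (from a
historical + projected birth-cohort schedule) or by immigration, and may
leave by emigration or death.  Each actor carries a sampling weight — the
number of real persons it represents — so that desk-scale runs (1e4–1e6
actors) aggregate to population totals.

Conventions
-----------
* Actors born or arriving during calendar year ``y`` become active at the
  following January 1; exact birth dates are continuous (uniform within
  the birth year), so integer age at any January 1 is
  ``floor(year - birth_time)``.
* Immigrants enter dementia-free and acquire dementia risk from arrival;
  emigration censors the lifecourse (no return).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SEXES = ("male", "female")

#: Exclusive upper bound on integer age at arrival for immigrants.
ARRIVAL_AGE_MAX = 95


class EmptyPopulationError(ValueError):
    """The demographic schedules imply no entrants at all."""


@dataclass
class CohortSchedule:
    """Births per (birth year, sex) over a contiguous span."""

    year_start: int
    births: np.ndarray  # (n_years, 2)
    projection_variant: str = "mid"

    def __post_init__(self):
        self.births = np.asarray(self.births, dtype=float)
        if self.births.ndim != 2 or self.births.shape[1] != 2:
            raise ValueError("cohort births must have shape (n_years, 2)")
        if np.any(self.births < 0):
            raise ValueError("cohort birth counts must be nonnegative")

    @property
    def year_end(self) -> int:
        return self.year_start + self.births.shape[0] - 1

    @classmethod
    def constant(cls, year_start, year_end, births_per_sex, **kw):
        n = year_end - year_start + 1
        return cls(year_start, np.full((n, 2), float(births_per_sex)), **kw)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortSchedule":
        years = np.sort(df["year"].unique())
        y0 = int(years[0])
        births = np.zeros((int(years[-1]) - y0 + 1, 2))
        births[df["year"].to_numpy(int) - y0, [_SEXES.index(s) for s in df["sex"]]] = df[
            "births"
        ].to_numpy(float)
        return cls(y0, births)

    def to_frame(self) -> pd.DataFrame:
        yi, si = np.meshgrid(np.arange(self.births.shape[0]), np.arange(2), indexing="ij")
        return pd.DataFrame(
            {
                "year": self.year_start + yi.ravel(),
                "sex": np.array(_SEXES)[si.ravel()],
                "births": self.births.ravel(),
            }
        )


@dataclass
class MigrationSchedule:
    """Immigration counts and emigration hazards.

    Immigration is a count per (calendar year, sex, age-at-arrival group);
    arrival ages are uniform over the integer ages of the group.
    Emigration is a hazard per person-year per (age group, sex, year).
    """

    year_start: int
    immigration: np.ndarray  # (n_years, 2, n_arrival_groups)
    emigration_rate: np.ndarray  # (n_emi_groups, 2, n_years)
    arrival_age_group_edges: tuple = (0, 20, 40, 65)
    emigration_age_group_edges: tuple = (0, 20, 40, 65)
    arrival_age_max: int = ARRIVAL_AGE_MAX

    def __post_init__(self):
        self.immigration = np.asarray(self.immigration, dtype=float)
        self.emigration_rate = np.asarray(self.emigration_rate, dtype=float)
        self.arrival_age_group_edges = tuple(int(e) for e in self.arrival_age_group_edges)
        self.emigration_age_group_edges = tuple(int(e) for e in self.emigration_age_group_edges)
        if np.any(self.immigration < 0):
            raise ValueError("immigration counts must be nonnegative")
        if np.any(self.emigration_rate < 0):
            raise ValueError("emigration rates must be nonnegative")
        if self.immigration.shape[1] != 2 or self.immigration.shape[2] != len(
            self.arrival_age_group_edges
        ):
            raise ValueError("immigration must have shape (n_years, 2, n_arrival_groups)")
        if self.emigration_rate.shape[0] != len(self.emigration_age_group_edges):
            raise ValueError("emigration_rate must have shape (n_groups, 2, n_years)")

    @property
    def n_years(self) -> int:
        return self.immigration.shape[0]

    @property
    def year_end(self) -> int:
        return self.year_start + self.n_years - 1

    @classmethod
    def constant(
        cls,
        year_start,
        year_end,
        immigration_per_year=0.0,
        arrival_age_group_edges=(0, 20, 40, 65),
        arrival_age_props=(0.30, 0.45, 0.20, 0.05),
        emigration_rate=0.0,
        emigration_age_group_edges=(0, 20, 40, 65),
    ):
        n = year_end - year_start + 1
        props = np.asarray(arrival_age_props, dtype=float)
        imm = np.tile(immigration_per_year * props / 2.0, (n, 2, 1))
        emi = np.full((len(emigration_age_group_edges), 2, n), float(emigration_rate))
        return cls(
            year_start,
            imm,
            emi,
            arrival_age_group_edges=arrival_age_group_edges,
            emigration_age_group_edges=emigration_age_group_edges,
        )

    def arrival_group_age_bounds(self, g: int) -> tuple[int, int]:
        """Integer-age range [lo, hi) for arrival group g."""
        edges = self.arrival_age_group_edges
        lo = edges[g]
        hi = edges[g + 1] if g + 1 < len(edges) else self.arrival_age_max
        return lo, hi

    def emigration_year_matrix(self, year: int) -> np.ndarray:
        """Per-age ``(2, 111)`` emigration hazard slice for one year (clamped)."""
        j = int(np.clip(year - self.year_start, 0, self.n_years - 1))
        gi = np.searchsorted(np.asarray(self.emigration_age_group_edges)[1:], np.arange(111), side="right")
        return self.emigration_rate[gi, :, j].T

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        from .parameters import age_group_labels  # local import avoids a cycle at module load

        albl = age_group_labels(self.arrival_age_group_edges)
        yi, si, gi = np.meshgrid(
            np.arange(self.n_years), np.arange(2), np.arange(len(albl)), indexing="ij"
        )
        imm = pd.DataFrame(
            {
                "year": self.year_start + yi.ravel(),
                "sex": np.array(_SEXES)[si.ravel()],
                "age_group": np.array(albl)[gi.ravel()],
                "count": self.immigration.ravel(),
            }
        )
        elbl = age_group_labels(self.emigration_age_group_edges)
        gi, si, yi = np.meshgrid(
            np.arange(len(elbl)), np.arange(2), np.arange(self.n_years), indexing="ij"
        )
        emi = pd.DataFrame(
            {
                "age_group": np.array(elbl)[gi.ravel()],
                "sex": np.array(_SEXES)[si.ravel()],
                "year": self.year_start + yi.ravel(),
                "value": self.emigration_rate.ravel(),
            }
        )
        return imm, emi

    @classmethod
    def from_frames(
        cls, imm_df, emi_df, arrival_age_group_edges, emigration_age_group_edges
    ) -> "MigrationSchedule":
        from .parameters import age_group_labels

        albl = age_group_labels(arrival_age_group_edges)
        years = np.sort(imm_df["year"].unique())
        y0 = int(years[0])
        n = int(years[-1]) - y0 + 1
        imm = np.zeros((n, 2, len(albl)))
        imm[
            imm_df["year"].to_numpy(int) - y0,
            [_SEXES.index(s) for s in imm_df["sex"]],
            [albl.index(g) for g in imm_df["age_group"]],
        ] = imm_df["count"].to_numpy(float)
        elbl = age_group_labels(emigration_age_group_edges)
        emi = np.zeros((len(elbl), 2, n))
        emi[
            [elbl.index(g) for g in emi_df["age_group"]],
            [_SEXES.index(s) for s in emi_df["sex"]],
            emi_df["year"].to_numpy(int) - y0,
        ] = emi_df["value"].to_numpy(float)
        return cls(
            y0,
            imm,
            emi,
            arrival_age_group_edges=tuple(arrival_age_group_edges),
            emigration_age_group_edges=tuple(emigration_age_group_edges),
        )


@dataclass
class ActorSeed:
    """One simulated person's entry record."""

    id: int
    sex: int  # 0 male, 1 female
    birth_time: float  # continuous calendar time of birth
    entry_mode: str  # "born" | "immigrant"
    entry_year: int  # first January 1 at which the actor is active
    weight: float  # persons represented by this actor


@dataclass
class ActorPopulation:
    """Column-oriented container of actor seeds (sequence of :class:`ActorSeed`)."""

    ids: np.ndarray
    sex: np.ndarray
    birth_time: np.ndarray
    entry_mode: np.ndarray  # 0 born, 1 immigrant
    entry_year: np.ndarray
    weight: float
    _modes: tuple = field(default=("born", "immigrant"), repr=False)

    def __len__(self) -> int:
        return self.ids.size

    def __getitem__(self, i) -> ActorSeed:
        return ActorSeed(
            id=int(self.ids[i]),
            sex=int(self.sex[i]),
            birth_time=float(self.birth_time[i]),
            entry_mode=self._modes[int(self.entry_mode[i])],
            entry_year=int(self.entry_year[i]),
            weight=float(self.weight),
        )

    def permuted(self, order) -> "ActorPopulation":
        """Same actors in a different storage order (ids travel with rows)."""
        order = np.asarray(order)
        return ActorPopulation(
            ids=self.ids[order],
            sex=self.sex[order],
            birth_time=self.birth_time[order],
            entry_mode=self.entry_mode[order],
            entry_year=self.entry_year[order],
            weight=self.weight,
        )


def build_actor_seeds(
    cohorts: CohortSchedule,
    migration: MigrationSchedule | None,
    n_actors: int,
    seed: int,
) -> ActorPopulation:
    """Sample actor entry records proportionally to the demographic schedules.

    Every actor carries the same weight, total represented persons divided
    by ``n_actors``; birth dates are uniform within the birth year, and
    immigrant arrival ages are uniform over the integer ages of the
    arrival group.  Deterministic for a fixed ``seed``.
    """
    if n_actors <= 0:
        raise EmptyPopulationError("n_actors must be positive")
    rows = []  # (kind, year, sex, group, count)
    for j in range(cohorts.births.shape[0]):
        for s in range(2):
            c = cohorts.births[j, s]
            if c > 0:
                rows.append((0, cohorts.year_start + j, s, -1, c))
    if migration is not None:
        for j in range(migration.n_years):
            for s in range(2):
                for g in range(migration.immigration.shape[2]):
                    c = migration.immigration[j, s, g]
                    if c > 0:
                        rows.append((1, migration.year_start + j, s, g, c))
    if not rows:
        raise EmptyPopulationError("empty population: all cohort and immigration counts are zero")
    counts = np.array([r[4] for r in rows])
    total = counts.sum()
    weight = total / n_actors

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_actors, p=counts / total)
    kind = np.array([rows[i][0] for i in idx], dtype=np.int8)
    year = np.array([rows[i][1] for i in idx], dtype=np.int64)
    sexv = np.array([rows[i][2] for i in idx], dtype=np.int8)
    grp = np.array([rows[i][3] for i in idx], dtype=np.int64)

    u_birth = rng.random(n_actors)
    birth_time = np.empty(n_actors)
    entry_year = year + 1  # active at the January 1 following birth/arrival

    born = kind == 0
    birth_time[born] = year[born] + u_birth[born]
    if np.any(~born):
        imm = ~born
        lo = np.empty(imm.sum())
        hi = np.empty(imm.sum())
        for k, g in enumerate(grp[imm]):
            l, h = migration.arrival_group_age_bounds(int(g))
            lo[k], hi[k] = l, h
        # integer age at entry uniform over the group; fractional birth date uniform
        age_int = np.floor(lo + rng.random(imm.sum()) * (hi - lo))
        birth_time[imm] = entry_year[imm] - age_int - u_birth[imm]

    return ActorPopulation(
        ids=np.arange(n_actors, dtype=np.int64),
        sex=sexv,
        birth_time=birth_time,
        entry_mode=kind,
        entry_year=entry_year,
        weight=float(weight),
    )


def baseline_mortality(model, age, sex, year):
    """Baseline (dementia-free) mortality hazard m0(a, s, t) of a mortality model."""
    return model.rate(age, sex, year)
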