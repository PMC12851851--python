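"""Data model, validated I/O, and temporal conventions for census, plant, and environment tables.

Time is carried everywhere as decimal years; censuses fall on a quarterly grid
(.00 / .25 / .50 / .75).  ISO dates in input files are converted as
``year + (day_of_year - 1) / 365.25``.

Three long-format CSV tables are understood:

* **census** — one row per (site, transect, quadrat, date) with laminarian
  life-stage counts, fractional turf covers and urchin densities;
* **plants** — either one row per plant-census observation (``long`` dialect)
  or one row per plant with a serialized stipe series (``wide`` dialect);
* **environment** — a timestamped temperature or wave series.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CENSUS_COLUMNS",
    "COUNT_COLUMNS",
    "COVER_COLUMNS",
    "ValidationError",
    "PlantRecord",
    "SiteMeta",
    "to_decimal_year",
    "load_census",
    "validate_census",
    "load_plants",
    "plants_to_frame",
    "lifespan",
    "add_lifespans",
    "load_env_series",
]

#: quarterly census cadence, in years
CENSUS_INTERVAL = 0.25

COUNT_COLUMNS = (
    "macro_adult",
    "macro_preadult",
    "macro_juvenile",
    "stipe_count",
    "stipitate",
    "laminate",
    "desmarestia",
)
COVER_COLUMNS = ("brown_turf", "red_turf", "articulated_coralline", "cystoseira")
URCHIN_COLUMNS = ("psu_density", "rsu_density")
KEY_COLUMNS = ("site_id", "transect_id", "quadrat_id", "date")
CENSUS_COLUMNS = KEY_COLUMNS + COUNT_COLUMNS + COVER_COLUMNS + URCHIN_COLUMNS


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def to_decimal_year(value) -> float:
    """Convert an ISO date / datetime / numeric string to a decimal year.

    Numeric input is passed through unchanged; ``"2001-07-02"`` becomes
    ``2001 + (182 - 1) / 365.25``.
    """
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    if isinstance(value, (_dt.date, _dt.datetime)):
        doy = value.timetuple().tm_yday
        return value.year + (doy - 1) / 365.25
    s = str(value).strip()
    try:
        return float(s)
    except ValueError:
        pass
    d = _dt.date.fromisoformat(s)
    return d.year + (d.timetuple().tm_yday - 1) / 365.25


# ---------------------------------------------------------------------------
# census table
# ---------------------------------------------------------------------------

def validate_census(df: pd.DataFrame) -> pd.DataFrame:
    """Check all census invariants; return the frame sorted by (site, date, transect, quadrat).

    Raises :class:`ValidationError` naming the first offending row index and
    field.
    """
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"census table missing columns: {missing}")
    for col in COUNT_COLUMNS:
        bad = df.index[(df[col] < 0) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValidationError(f"row {bad[0]}: field '{col}' must be a non-negative count")
    for col in COVER_COLUMNS:
        bad = df.index[(df[col] < 0) | (df[col] > 1) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValidationError(f"row {bad[0]}: field '{col}' outside [0, 1]")
    for col in URCHIN_COLUMNS:
        bad = df.index[(df[col] < 0) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValidationError(f"row {bad[0]}: field '{col}' must be non-negative")
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        raise ValidationError(
            f"row {df.index[dup][0]}: duplicate (site, transect, quadrat, date) key"
        )
    return df.sort_values(["site_id", "date", "transect_id", "quadrat_id"]).reset_index(drop=True)


def load_census(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a census CSV, convert dates to decimal years, and validate.

    ``dialect`` may map non-standard header names onto the canonical
    :data:`CENSUS_COLUMNS` names.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    if "date" in df.columns:
        df["date"] = df["date"].map(to_decimal_year)
    return validate_census(df)


# ---------------------------------------------------------------------------
# plant records
# ---------------------------------------------------------------------------

@dataclass
class PlantRecord:
    """One adult plant tracked from adult recruitment to death or censoring.

    ``dead=False`` means the plant was still present at its site's final
    census (right-censored).  ``stipe_series`` is an ordered list of
    ``(decimal_year, stipe_count)`` pairs; the first count must be >= 4
    (the adulthood criterion: plants with at least four stipes).
    """

    plant_id: str
    site_id: str
    quadrat_id: str
    recruit_date: float
    last_date: float
    dead: bool
    stipe_series: list[tuple[float, int]] = field(default_factory=list)
    cohort_id: str | None = None

    def __post_init__(self):
        if self.last_date < self.recruit_date:
            raise ValidationError(
                f"plant {self.plant_id}: last_date {self.last_date} < recruit_date {self.recruit_date}"
            )
        if self.stipe_series:
            dates = [t for t, _ in self.stipe_series]
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValidationError(f"plant {self.plant_id}: non-monotone stipe series dates")
            if self.stipe_series[0][1] < 4:
                raise ValidationError(
                    f"plant {self.plant_id}: stipe count {self.stipe_series[0][1]} < 4 at recruitment"
                )

    @property
    def n_observations(self) -> int:
        return max(len(self.stipe_series), 1)

    @property
    def max_stipes(self) -> int:
        if not self.stipe_series:
            return 0
        return max(s for _, s in self.stipe_series)


@dataclass
class SiteMeta:
    """Static site attributes: depth (m, 8-21), year established, physiography."""

    site_id: str
    depth: float
    year_established: int
    physiography: str = ""

    def __post_init__(self):
        if not 8 <= self.depth <= 21:
            raise ValidationError(f"site {self.site_id}: depth {self.depth} outside [8, 21] m")


def _assemble_long(df: pd.DataFrame, final_dates: dict[str, float]) -> list[PlantRecord]:
    records = []
    for pid, grp in df.groupby("plant_id", sort=True):
        grp = grp.sort_values("date")
        sites = grp["site_id"].unique()
        if len(sites) > 1:
            raise ValidationError(f"plant {pid}: observed at more than one site {list(sites)}")
        site = sites[0]
        series = list(zip(grp["date"].astype(float), grp["stipes"].astype(int)))
        last = series[-1][0]
        final = final_dates[site]
        records.append(
            PlantRecord(
                plant_id=str(pid),
                site_id=str(site),
                quadrat_id=str(grp["quadrat_id"].iloc[0]),
                recruit_date=series[0][0],
                last_date=last,
                dead=last < final - 1e-9,
                stipe_series=series,
            )
        )
    return records


def load_plants(path, dialect: str = "long", site_final_dates: dict[str, float] | None = None) -> list[PlantRecord]:
    """Read a plant CSV in either dialect and assemble :class:`PlantRecord` objects.

    ``long`` dialect: columns plant_id, site_id, quadrat_id, date, stipes —
    one row per plant-census observation.  ``wide`` dialect: one row per
    plant with a ``stipe_series`` column serialized ``"date:stipes;..."``.

    The dead flag is derived: a plant absent at a later census is dead at the
    first missed census; a plant present at its site's final census is
    right-censored.  ``site_final_dates`` overrides the per-site final census
    date (default: maximum observed date at the site).
    """
    df = pd.read_csv(path)
    if dialect == "long":
        df["date"] = df["date"].map(to_decimal_year)
        if df.duplicated(subset=["plant_id", "date"]).any():
            raise ValidationError("duplicate (plant_id, date) observation")
        finals = site_final_dates or df.groupby("site_id")["date"].max().to_dict()
        return _assemble_long(df, finals)
    if dialect == "wide":
        if df["plant_id"].duplicated().any():
            dup = df.loc[df["plant_id"].duplicated(), "plant_id"].iloc[0]
            raise ValidationError(f"two plants share plant_id {dup!r}")
        records = []
        finals = site_final_dates or {}
        if not finals:
            for _, row in df.iterrows():
                pairs = [p for p in str(row["stipe_series"]).split(";") if p]
                last = float(pairs[-1].split(":")[0])
                finals[row["site_id"]] = max(finals.get(row["site_id"], -np.inf), last)
        for _, row in df.iterrows():
            series = []
            for pair in str(row["stipe_series"]).split(";"):
                if not pair:
                    continue
                t, s = pair.split(":")
                series.append((float(t), int(s)))
            last = series[-1][0]
            records.append(
                PlantRecord(
                    plant_id=str(row["plant_id"]),
                    site_id=str(row["site_id"]),
                    quadrat_id=str(row["quadrat_id"]),
                    recruit_date=series[0][0],
                    last_date=last,
                    dead=last < finals[row["site_id"]] - 1e-9,
                    stipe_series=series,
                )
            )
        return records
    raise ValueError(f"unknown plant-table dialect {dialect!r}")


def plants_to_frame(plants: list[PlantRecord]) -> pd.DataFrame:
    """Flatten plant records to one row per plant (stipe series summarized)."""
    return pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in plants],
            "site_id": [p.site_id for p in plants],
            "quadrat_id": [p.quadrat_id for p in plants],
            "recruit_date": [p.recruit_date for p in plants],
            "last_date": [p.last_date for p in plants],
            "dead": [p.dead for p in plants],
            "n_observations": [p.n_observations for p in plants],
            "max_stipes": [p.max_stipes for p in plants],
            "cohort_id": [p.cohort_id for p in plants],
        }
    )


# ---------------------------------------------------------------------------
# lifespans
# ---------------------------------------------------------------------------

def lifespan(
    plant: PlantRecord,
    convention: str = "midpoint",
    census_interval: float = CENSUS_INTERVAL,
) -> tuple[float, bool]:
    """Duration from adult recruitment to death (or censoring) in years, plus event flag.

    Death occurs somewhere between the last census a plant was seen and the
    first census it was missed.  The interval-censored death time is resolved
    per ``convention``:

    * ``"midpoint"`` (default) — halfway between the two censuses,
    * ``"last-seen"`` — the last observation date,
    * ``"first-missed"`` — the first missed census.

    Censored plants contribute ``last_date - recruit_date`` with event=False.
    """
    if not plant.dead:
        return plant.last_date - plant.recruit_date, False
    first_missed = plant.last_date + census_interval
    if convention == "midpoint":
        death = 0.5 * (plant.last_date + first_missed)
    elif convention == "last-seen":
        death = plant.last_date
    elif convention == "first-missed":
        death = first_missed
    else:
        raise ValueError(f"unknown lifespan convention {convention!r}")
    return death - plant.recruit_date, True


def add_lifespans(
    plants: list[PlantRecord],
    convention: str = "midpoint",
    census_interval: float = CENSUS_INTERVAL,
) -> pd.DataFrame:
    """Per-plant frame with ``duration`` (years) and ``event`` columns."""
    df = plants_to_frame(plants)
    durs, events = [], []
    for p in plants:
        d, e = lifespan(p, convention=convention, census_interval=census_interval)
        durs.append(d)
        events.append(e)
    df["duration"] = durs
    df["event"] = events
    return df


# ---------------------------------------------------------------------------
# environment series
# ---------------------------------------------------------------------------

def load_env_series(path, kind: str) -> pd.DataFrame:
    """Read a temperature (columns time, temperature) or wave (time, hs, period) CSV."""
    df = pd.read_csv(path)
    df["time"] = df["time"].map(to_decimal_year)
    if not df["time"].is_monotonic_increasing or df["time"].duplicated().any():
        raise ValidationError("environment series timestamps must be strictly increasing")
    if kind == "temperature":
        if "temperature" not in df.columns:
            raise ValidationError("temperature series needs a 'temperature' column")
    elif kind == "wave":
        if "hs" not in df.columns or "period" not in df.columns:
            raise ValidationError("wave series needs 'hs' and 'period' columns")
        if (df["hs"] < 0).any():
            raise ValidationError("hs must be non-negative")
        if (df["period"] <= 0).any():
            raise ValidationError("period must be positive")
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    return df.reset_index(drop=True)
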