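"""Cohort detection from adult-recruitment pulses and cohort parameter extraction.

A *cohort window* is a maximal run of adult-recruitment events at a site
separated from other runs by at least one year; pulses typically span less
than 18 months, so longer windows are kept but flagged ``extended``.  A
cohort is *pulsed* when at least 80% of its plants recruited to adulthood
within the first year after its first plant appeared and its recruitment is
at least one year distinct from neighboring cohorts; otherwise it is
*trickled*.  A cohort is *blended* when at least one plant of any previous
cohort at the site is still alive at its onset.

``cohort_parameters`` assembles the full per-cohort parameter vector used by
the downstream factor analysis and additive models: plant count N, singles
(adults observed at exactly one census), pre-adults and juveniles within one
year before onset, previously existing adults (potential spore provisioning),
understory within one year of onset, mean lifespan, mean per-plant maximum
stipe count, Kaplan-Meier survivorship quantiles, the 80th percentiles of
bottom temperature and wave energy over the cohort's lifetime (onset to the
95% survival quantile), sea urchin densities, depth, and calendar decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CENSUS_INTERVAL, PlantRecord, add_lifespans
from .environment import window_quantile
from .survival import km_fit, km_quantile

__all__ = [
    "CohortWindow",
    "detect_cohort_windows",
    "assign_plants",
    "classify_pulse",
    "detect_blending",
    "juvenile_response",
    "cohort_parameters",
    "cohort_parameter_table",
    "attribute_mortality",
]


@dataclass
class CohortWindow:
    site_id: str
    cohort_number: int        # 1-based per site, in time order
    start: float              # first adult recruit (decimal years)
    end: float                # last adult recruit in window
    extended: bool = False    # span >= max_pulse (advisory flag, not a split)

    @property
    def cohort_id(self) -> str:
        return f"{self.site_id}-{self.cohort_number}"

    @property
    def span(self) -> float:
        return self.end - self.start


def detect_cohort_windows(
    recruit_dates,
    site_id: str = "site",
    max_pulse: float = 1.5,
    min_gap: float = 1.0,
) -> list[CohortWindow]:
    """Partition a site's adult-recruitment dates into cohort windows.

    Events are split at every inter-event gap >= ``min_gap`` (1 year); each
    resulting segment is one window.  Segments spanning >= ``max_pulse``
    (18 months) are retained but flagged ``extended``.  An isolated single
    recruit forms a singleton window.
    """
    dates = np.sort(np.asarray(list(recruit_dates), dtype=float))
    if dates.size == 0:
        return []
    windows = []
    seg_start = dates[0]
    prev = dates[0]
    number = 1
    for d in dates[1:]:
        if d - prev >= min_gap - 1e-9:
            windows.append(CohortWindow(site_id, number, seg_start, prev,
                                        extended=(prev - seg_start) >= max_pulse - 1e-9))
            number += 1
            seg_start = d
        prev = d
    windows.append(CohortWindow(site_id, number, seg_start, prev,
                                extended=(prev - seg_start) >= max_pulse - 1e-9))
    return windows


def assign_plants(
    windows: list[CohortWindow],
    plants: list[PlantRecord],
) -> tuple[dict[str, list[PlantRecord]], list[PlantRecord]]:
    """Assign each plant to the window containing its recruit date.

    Returns (rosters keyed by cohort_id, unassigned plants).  Windows are
    built from the same recruit dates, so unassigned plants indicate an
    input inconsistency and are reported rather than silently dropped.
    Overlapping windows violate the construction and raise.
    """
    for a, b in zip(windows, windows[1:]):
        if b.start <= a.end + 1e-9:
            raise ValueError(f"overlapping cohort windows {a.cohort_id} and {b.cohort_id}")
    rosters: dict[str, list[PlantRecord]] = {w.cohort_id: [] for w in windows}
    unassigned = []
    for p in plants:
        placed = False
        for w in windows:
            if w.start - 1e-9 <= p.recruit_date <= w.end + 1e-9:
                p.cohort_id = w.cohort_id
                rosters[w.cohort_id].append(p)
                placed = True
                break
        if not placed:
            unassigned.append(p)
    return rosters, unassigned


def classify_pulse(
    roster: list[PlantRecord],
    window: CohortWindow,
    prev_window: CohortWindow | None = None,
    next_window: CohortWindow | None = None,
    first_year_fraction: float = 0.80,
    min_gap: float = 1.0,
) -> str:
    """'pulsed' or 'trickled' per the inclusive 80%-in-first-year rule.

    Pulsed requires (a) the fraction of plants recruiting within one year of
    the cohort's first plant to be at least ``first_year_fraction`` and (b)
    recruitment distinct from neighboring cohorts by at least ``min_gap``
    years on both sides (series edges count as satisfied).
    """
    if not roster:
        raise ValueError("empty cohort roster")
    dates = np.array([p.recruit_date for p in roster])
    frac = float(np.mean(dates <= window.start + 1.0 + 1e-9))
    distinct = True
    if prev_window is not None and window.start - prev_window.end < min_gap - 1e-9:
        distinct = False
    if next_window is not None and next_window.start - window.end < min_gap - 1e-9:
        distinct = False
    return "pulsed" if (frac >= first_year_fraction - 1e-12 and distinct) else "trickled"


def _death_time(p: PlantRecord, convention: str = "midpoint") -> float:
    """Resolved death time; +inf for censored plants (alive through the series)."""
    if not p.dead:
        return np.inf
    first_missed = p.last_date + CENSUS_INTERVAL
    if convention == "midpoint":
        return 0.5 * (p.last_date + first_missed)
    if convention == "last-seen":
        return p.last_date
    return first_missed


def detect_blending(
    windows: list[CohortWindow],
    rosters: dict[str, list[PlantRecord]],
    convention: str = "midpoint",
) -> dict[str, bool]:
    """Cohort is blended iff >= 1 plant of any previous cohort is alive at its onset."""
    out = {}
    for i, w in enumerate(windows):
        survivors = 0
        for prev in windows[:i]:
            for p in rosters[prev.cohort_id]:
                if _death_time(p, convention) > w.start:
                    survivors += 1
        out[w.cohort_id] = survivors >= 1
    return out


def _mortality_quantile_date(roster, q: float, convention: str = "midpoint") -> float | None:
    """Date at which cumulative mortality of a roster first reaches fraction q.

    None when censoring prevents mortality from verifiably reaching q.
    """
    deaths = np.sort([_death_time(p, convention) for p in roster])
    need = int(np.ceil(q * len(roster) - 1e-9))
    need = max(need, 1)
    t = deaths[need - 1]
    return None if np.isinf(t) else float(t)


def juvenile_response(
    cohort_window: CohortWindow,
    predecessor_roster: list[PlantRecord],
    census: pd.DataFrame,
    dieoff_fraction: float = 0.95,
    lag: float = 0.25,
    convention: str = "midpoint",
) -> bool | None:
    """Did juveniles appear within 3 months of >= 95% die-off of the preceding cohort?

    The site juvenile count must rise above its pre-die-off baseline within
    ``lag`` years (one census) after the date the predecessor's cumulative
    mortality first reaches ``dieoff_fraction``.  Returns None
    (not applicable) when the predecessor never verifiably reaches that
    mortality level before the cohort's onset.
    """
    if not predecessor_roster:
        raise ValueError("juvenile_response requires a predecessor cohort")
    t95 = _mortality_quantile_date(predecessor_roster, dieoff_fraction, convention)
    if t95 is None or t95 > cohort_window.start + 1e-9:
        return None
    site = census[census["site_id"] == cohort_window.site_id]
    juv = site.groupby("date")["macro_juvenile"].sum().sort_index()
    before = juv[juv.index <= t95 + 1e-9]
    baseline = float(before.iloc[-1]) if len(before) else 0.0
    after = juv[(juv.index > t95 + 1e-9) & (juv.index <= t95 + lag + 1e-9)]
    return bool((after > baseline).any())


def cohort_parameters(
    window: CohortWindow,
    roster: list[PlantRecord],
    census: pd.DataFrame,
    scaled_guilds: pd.DataFrame,
    temperature: pd.DataFrame,
    wave_energy_series: pd.DataFrame,
    all_windows: list[CohortWindow] | None = None,
    all_rosters: dict[str, list[PlantRecord]] | None = None,
    depth: float = np.nan,
    convention: str = "midpoint",
    covariate_quantile: float = 0.80,
) -> dict:
    """Assemble the full parameter vector for one cohort.

    Covariate windows: pre-adults, juveniles, previously existing adults and
    understory are taken over the year *before* onset (these condition adult
    recruitment); temperature/wave-energy quantiles and urchin densities are
    taken over [onset, onset + t95], with t95 the cohort's Kaplan-Meier 95%
    survival quantile (maximum observed duration when undefined).
    """
    if not roster:
        raise ValueError("empty cohort roster")
    onset = window.start
    lt = add_lifespans(roster, convention=convention)
    durations = lt["duration"].to_numpy()
    events = lt["event"].to_numpy()
    curve = km_fit(durations, events)
    kmq = {p: km_quantile(curve, p) for p in (0.25, 0.5, 0.75, 0.95)}
    t95 = kmq[0.95]
    if np.isnan(t95):
        t95 = float(durations.max())
    t95 = max(t95, CENSUS_INTERVAL)

    site_census = census[census["site_id"] == window.site_id]
    pre = site_census[(site_census["date"] >= onset - 1.0 - 1e-9) & (site_census["date"] <= onset + 1e-9)]
    by_date = pre.groupby("date")[["macro_preadult", "macro_juvenile"]].sum()
    pa = int(by_date["macro_preadult"].max()) if len(by_date) else 0
    juv1 = int(by_date["macro_juvenile"].max()) if len(by_date) else 0

    ad = 0
    if all_windows is not None and all_rosters is not None:
        for prev in all_windows:
            if prev.start >= window.start:
                continue
            for p in all_rosters[prev.cohort_id]:
                alive_until = min(_death_time(p, convention), onset)
                # alive at any census in [onset - 1, onset)
                if alive_until > onset - 1.0 and p.recruit_date < onset:
                    ad += 1

    guild_site = scaled_guilds[scaled_guilds["site_id"] == window.site_id]
    gpre = guild_site[(guild_site["date"] >= onset - 1.0 - 1e-9) & (guild_site["date"] <= onset + 1e-9)]
    understory_cols = ["stipitate", "laminate", "brown_turf", "red_turf",
                       "articulated_coralline", "desmarestia"]
    understory_1yr = float(gpre[understory_cols].sum(axis=1).mean()) if len(gpre) else np.nan
    cover_cols = ["brown_turf", "red_turf", "articulated_coralline", "cystoseira"]
    understory_cover_1yr = float(pre[cover_cols].sum(axis=1).mean()) if len(pre) else np.nan

    cov_window = (onset, onset + t95 + 1e-9)
    temp80 = window_quantile(temperature, cov_window, covariate_quantile, "temperature")
    wave80 = window_quantile(wave_energy_series, cov_window, covariate_quantile, "energy")
    life = site_census[(site_census["date"] >= onset) & (site_census["date"] < onset + t95 + 1e-9)]
    urch = life.groupby("date")[["psu_density", "rsu_density"]].mean()
    psu = float(urch["psu_density"].mean()) if len(urch) else np.nan
    rsu = float(urch["rsu_density"].mean()) if len(urch) else np.nan

    return {
        "cohort_id": window.cohort_id,
        "site_id": window.site_id,
        "cohort_number": window.cohort_number,
        "onset_date": onset,
        "N": len(roster),
        "singles": int(sum(p.n_observations == 1 for p in roster)),
        "PA": pa,
        "juveniles_1yr": juv1,
        "Ad": ad,
        "understory_1yr": understory_1yr,
        "understory_cover_1yr": understory_cover_1yr,
        "life_mn": float(durations.mean()),
        "st_max_mn": float(np.mean([p.max_stipes for p in roster])),
        "km_q25": kmq[0.25],
        "km_q50": kmq[0.5],
        "km_q75": kmq[0.75],
        "km_q95": kmq[0.95],
        "t95": t95,
        "depth": depth,
        "decade": f"{int(onset) // 10 * 10}s",
        "psu_density": psu,
        "rsu_density": rsu,
        "temp80": temp80,
        "wave80": wave80,
        "n_censored": int((~events).sum()),
        "alive": bool((~events).any()),
        "extended": window.extended,
    }


def cohort_parameter_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-cohort parameter dicts into the cohort-parameter matrix."""
    return pd.DataFrame(rows)


def attribute_mortality(
    roster: list[PlantRecord],
    temperature: pd.DataFrame,
    wave_energy_series: pd.DataFrame,
    census_site: pd.DataFrame,
    heat_threshold: float = 18.0,
    wave_threshold: float = 6800.0,
    psu_threshold: float = 2.5,
    rsu_threshold: float = 0.25,
    min_n: int = 5,
    convention: str = "midpoint",
) -> str:
    """Rule-based approximation of the mortality cause over a cohort's terminal phase.

    The terminal phase is the interval over which cumulative mortality rises
    from 50% to 95%.  Heat fires when the 80th percentile of bottom
    temperature over the phase exceeds ``heat_threshold``; waves when any
    weekly energy exceeds ``wave_threshold`` (J m^-2); sea urchins when mean
    purple-urchin density exceeds 2.5 m^-2 or red-urchin density 0.25 m^-2.
    Cohorts smaller than ``min_n`` are labeled "small cohort".  When several
    rules fire the two highest-priority causes (heat > waves > urchins) are
    joined; when none fires the label is "not known".  This is an explicit
    rule-based stand-in for a field-note judgment.
    """
    if len(roster) < min_n:
        return "small cohort"
    t50 = _mortality_quantile_date(roster, 0.50, convention)
    t95 = _mortality_quantile_date(roster, 0.95, convention)
    if t50 is None or t95 is None:
        return "not known"
    lo, hi = t50, max(t95, t50 + CENSUS_INTERVAL)
    causes = []
    try:
        if window_quantile(temperature, (lo, hi + 1e-9), 0.80, "temperature") > heat_threshold:
            causes.append("heat")
    except ValueError:
        pass
    w = wave_energy_series
    in_phase = w[(w["time"] >= lo) & (w["time"] < hi + 1e-9)]
    if len(in_phase) and (in_phase["energy"] > wave_threshold).any():
        causes.append("waves")
    phase_census = census_site[(census_site["date"] >= lo) & (census_site["date"] <= hi + 1e-9)]
    if len(phase_census):
        if (phase_census.groupby("date")["psu_density"].mean() > psu_threshold).any() or (
            phase_census.groupby("date")["rsu_density"].mean() > rsu_threshold
        ).any():
            causes.append("sea urchins")
    if not causes:
        return "not known"
    return "/".join(causes[:2])
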