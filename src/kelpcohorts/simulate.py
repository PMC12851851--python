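"""Individual-based simulator for kelp-forest census, plant, and environment tables.

The generator emulates the structure of a multi-decade quarterly monitoring
program: 20 sites (depths 8-21 m) x 4 transects x 10 quadrats of 10 m^2,
censused quarterly, with a single shared bottom-temperature logger (3-h
cadence) and wave hindcast.  Dynamics per quadrat:

* juveniles recruit when canopy is open (low adult density) and understory
  cover is low, mature through a pre-adult stage, and enter the adult table
  with >= 4 stipes;
* adult mortality is discrete-time survival with per-quarter hazard
  ``h0 * exp(bT * temp_anomaly + bW * 1[storm] + bU * urchins)`` plus a
  first-year self-thinning excess, so the Kaplan-Meier oracle stays exact;
* understory encroaches logistically when canopy is low and is knocked back
  by storms; *Desmarestia* blooms briefly after disturbance;
* stipe counts per plant rise toward a plant-specific maximum and then
  senesce.

Three recruitment regimes are available: ``"disturbance"`` (mechanistic,
cohorts emerge from canopy clearing), ``"planted"`` (explicit pulse windows
with known spacing/span, every quarter inside a window produces recruits —
the ground-truth regime for detector checks), and ``"trickled"``
(continuous low-rate adult recruitment).

All tables pass :mod:`kelpcohorts.core_data` validation, and a
:class:`GroundTruth` object records the planted windows, memberships, and
effect sizes.  Every stochastic draw flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_data import PlantRecord
from .environment import wave_energy, weekly_decimate

__all__ = [
    "DisturbanceEvent",
    "SimulationConfig",
    "GroundTruth",
    "default_schedule",
    "simulate_forcing",
    "simulate_site",
    "simulate_cohort_table",
    "make_fixture",
    "FIXTURES",
]

TABLE1_DEPTHS = (17, 16, 16, 12, 15, 18, 12, 15, 18, 18, 8, 12, 15, 18, 21, 15, 18, 12, 15, 18)


@dataclass
class DisturbanceEvent:
    time: float
    kind: str          # "heat" or "storm"
    magnitude: float   # degC anomaly peak, or storm H_s in m
    duration: float    # years


def default_schedule() -> list[DisturbanceEvent]:
    """The disturbance history the study region experienced: El Nino heat events
    of 1983, 1997/98 and the 2014-2016 marine heat wave; damaging storms of
    1983, 1988 (the largest), 1992, 2016, 2021, and 2023."""
    return [
        DisturbanceEvent(1983.2, "heat", 2.5, 1.0),
        DisturbanceEvent(1983.1, "storm", 4.2, 0.05),
        DisturbanceEvent(1988.05, "storm", 5.0, 0.04),
        DisturbanceEvent(1992.05, "storm", 3.8, 0.04),
        DisturbanceEvent(1997.7, "heat", 2.5, 1.0),
        DisturbanceEvent(2006.0, "heat", 1.5, 0.7),
        DisturbanceEvent(2015.0, "heat", 3.0, 1.5),
        DisturbanceEvent(2016.05, "storm", 4.0, 0.04),
        DisturbanceEvent(2021.05, "storm", 3.7, 0.04),
        DisturbanceEvent(2023.05, "storm", 3.8, 0.04),
    ]


@dataclass
class SimulationConfig:
    """Study-design and process parameters for the synthetic monitoring program.

    Defaults mirror the sampling design being emulated (20 sites, 4 transects
    x 10 quadrats, quarterly censuses 1983-2023) and produce pooled survival
    on the scale observed in long-term monitoring (median lifespan under a
    year, maxima near a decade).
    """

    seed: int
    n_sites: int = 20
    n_transects: int = 4
    n_quadrats: int = 10           # per transect
    start_year: float = 1983.0
    years: float = 40.0
    cadence: float = 0.25
    depths: tuple = TABLE1_DEPTHS
    schedule: list[DisturbanceEvent] = field(default_factory=default_schedule)
    regime: str = "disturbance"    # disturbance | planted | trickled
    # planted-pulse regime
    n_pulses: int = 6
    pulse_spacing: float = 1.5     # gap between window end and next start (yr)
    pulse_span: float = 0.75       # recruitment span within a window (yr)
    recruits_per_quarter: float = 4.0
    # mortality (per-year log-hazard scale)
    baseline_hazard: float = 0.35
    thinning_hazard: float = 0.5   # first-year excess (self-thinning)
    temp_coef: float = 0.6         # per degC anomaly
    wave_coef: float = 2.5         # on 1[weekly energy > wave threshold]
    urchin_coef: float = 0.25      # per purple urchin m^-2
    wave_threshold: float = 6800.0
    # recruitment / competition
    recruit_rate: float = 5.0      # juveniles per quadrat-quarter at full light/space
    light_capacity: float = 6.0    # adults per quadrat closing the canopy
    stand_close_at: float = 0.18   # site canopy fraction above which the stand self-shades
    stand_open_at: float = 0.06    # site canopy fraction below which recruitment reopens
    maturation_prob: float = 0.8   # per-quarter pre-adult maturation when the stand is open
    understory_rate: float = 1.2   # logistic encroachment per year
    understory_decay: float = 0.8  # canopy suppression of understory per year
    urchin_baseline: float = 0.4   # purple urchins m^-2
    urchin_outbreak_sites: tuple = (17,)   # site indices with grazing episodes
    temp_noise_sd: float = 0.6     # degC; 0 gives a noise-free seasonal cycle

    def __post_init__(self):
        if self.years <= 0 or self.cadence <= 0:
            raise ValueError("spans must be positive")
        if abs((1.0 / self.cadence) - round(1.0 / self.cadence)) > 1e-9:
            raise ValueError("census cadence must divide 1 year")


@dataclass
class GroundTruth:
    windows: list[tuple[float, float]]            # true (start, end) recruitment windows
    memberships: dict[str, int]                   # plant_id -> window index
    pulsed_labels: list[str]                      # per window
    effects: dict[str, float]                     # planted log-hazard coefficients
    canopy: pd.DataFrame = None                   # site mean adults per quadrat over time
    understory: pd.DataFrame = None               # site mean understory cover over time


# ---------------------------------------------------------------------------
# forcing
# ---------------------------------------------------------------------------

def simulate_forcing(config: SimulationConfig, seed: int | None = None):
    """Shared temperature (3-h) and wave (daily) series for all sites.

    Temperature = seasonal sinusoid + AR(1) noise + Gaussian warm-anomaly
    bumps from the heat events in the schedule (the known anomaly is kept in
    an extra ``anomaly`` column as ground truth).  Waves = Weibull-like daily
    H_s with a winter modulation plus storm spikes.  Deterministic given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t0, t1 = config.start_year, config.start_year + config.years
    step = 3.0 / (24 * 365.25)
    t = np.arange(t0, t1, step)
    seasonal = 15.0 + 3.5 * np.sin(2 * np.pi * (t - 0.28))
    rho = np.exp(-step / (10.0 / 365.25))  # ~10-day decorrelation
    eps = rng.normal(0, config.temp_noise_sd * np.sqrt(1 - rho**2), len(t))
    noise = lfilter([1.0], [1.0, -rho], eps)
    anomaly = noise.copy()
    for ev in config.schedule:
        if ev.kind == "heat":
            # flat-topped bump: near ev.magnitude across the event duration,
            # smooth shoulders (super-Gaussian)
            sigma = max(ev.duration / 2.0, 1e-3)
            anomaly += ev.magnitude * np.exp(-0.5 * ((t - ev.time) / sigma) ** 8)
    temp = pd.DataFrame({"time": t, "temperature": seasonal + anomaly, "anomaly": anomaly})

    td = np.arange(t0, t1, 1.0 / 365.25)
    season = 1.0 + 0.35 * np.cos(2 * np.pi * (td - 0.05))
    hs = rng.weibull(1.6, len(td)) * 0.9 * season
    for ev in config.schedule:
        if ev.kind == "storm":
            m = (td >= ev.time) & (td < ev.time + max(ev.duration, 1.5 / 365.25))
            hs[m] = ev.magnitude + rng.normal(0, 0.15, m.sum())
    hs = np.clip(hs, 0.05, None)
    period = np.clip(8.0 + 1.5 * hs + rng.normal(0, 1.0, len(td)), 4.0, 22.0)
    waves = pd.DataFrame({"time": td, "hs": hs, "period": period})
    return temp, waves


# ---------------------------------------------------------------------------
# site simulation
# ---------------------------------------------------------------------------

class _Plant:
    __slots__ = ("pid", "quadrat", "recruit_date", "stipes", "max_target", "alive",
                 "series", "window")

    def __init__(self, pid, quadrat, recruit_date, s0, max_target, window):
        self.pid = pid
        self.quadrat = quadrat
        self.recruit_date = recruit_date
        self.stipes = s0
        self.max_target = max_target
        self.alive = True
        self.series: list[tuple[float, int]] = []
        self.window = window


def _planted_windows(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    windows = []
    t = config.start_year + 1.0
    end = config.start_year + config.years - 1.0
    for _ in range(config.n_pulses):
        span = round(rng.uniform(0.25, config.pulse_span) / config.cadence) * config.cadence
        if t + span > end:
            break
        windows.append((round(t / 0.25) * 0.25, round((t + span) / 0.25) * 0.25))
        t = windows[-1][1] + config.pulse_spacing + rng.uniform(0, 0.5)
    return windows


def simulate_site(
    config: SimulationConfig,
    site_index: int = 0,
    forcing: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    seed: int | None = None,
):
    """Simulate one site; returns (census frame, plant records, GroundTruth).

    Stochastic draws come from ``seed`` (default: config.seed + site_index).
    """
    rng = np.random.default_rng(config.seed + site_index if seed is None else seed)
    if forcing is None:
        forcing = simulate_forcing(config, seed=config.seed)
    temp, waves = forcing
    depth = config.depths[site_index % len(config.depths)]
    site_id = f"S{site_index + 1:02d}"
    depth_factor = 1.0 + 0.06 * (15.0 - depth)     # shallower -> warmer, wavier
    wave_factor = max(0.3, 1.0 + 0.08 * (15.0 - depth))

    dates = np.round(np.arange(config.start_year, config.start_year + config.years,
                               config.cadence) / 0.25) * 0.25
    # quarterly aggregates of forcing
    ta, tt = temp["anomaly"].to_numpy(), temp["time"].to_numpy()
    weekly = weekly_decimate(waves)
    wt, we = weekly["time"].to_numpy(), weekly["energy"].to_numpy()
    anom_q, storm_q = [], []
    for d in dates:
        m = (tt >= d) & (tt < d + config.cadence)
        anom_q.append(ta[m].mean() if m.any() else 0.0)
        m2 = (wt >= d) & (wt < d + config.cadence)
        emax = we[m2].max() if m2.any() else 0.0
        storm_q.append(emax * wave_factor > config.wave_threshold)
    anom_q = np.array(anom_q)
    storm_q = np.array(storm_q)

    n_quads = config.n_transects * config.n_quadrats
    quad_keys = [(tr + 1, q + 1) for tr in range(config.n_transects) for q in range(config.n_quadrats)]
    understory = rng.uniform(0.02, 0.10, n_quads)
    juveniles = np.zeros(n_quads, dtype=int)
    preadults = np.zeros(n_quads, dtype=int)
    desmarestia_pool = np.zeros(n_quads)
    plants: list[_Plant] = []
    next_id = 1

    windows = _planted_windows(config, rng) if config.regime == "planted" else []
    outbreak = site_index in config.urchin_outbreak_sites
    psu_series = np.clip(config.urchin_baseline +
                         lfilter([1.0], [1.0, -0.9], rng.normal(0, 0.25, len(dates))), 0.02, None)
    if outbreak:
        k = len(dates) // 2
        psu_series[k:k + 12] += 4.0
    rsu_series = np.clip(psu_series * 0.08 + rng.normal(0, 0.02, len(dates)), 0.0, None)

    census_rows = []
    canopy_tl, under_tl = [], []
    disturb_times = [ev.time for ev in config.schedule]
    stand_open = True  # stand-scale self-shading state (hysteresis)

    for qi, d in enumerate(dates):
        canopy_per_quad = np.zeros(n_quads)
        for p in plants:
            if p.alive:
                canopy_per_quad[p.quadrat] += 1

        in_window = None
        for wi, (a, b) in enumerate(windows):
            if a - 1e-9 <= d <= b + 1e-9:
                in_window = wi
                break

        # --- recruitment of new adults ---
        new_adults = np.zeros(n_quads, dtype=int)
        if config.regime == "planted":
            if in_window is not None:
                total = rng.poisson(config.recruits_per_quarter) + 1
                for _ in range(total):
                    new_adults[rng.integers(n_quads)] += 1
        elif config.regime == "trickled":
            for q in range(n_quads):
                lam = 0.15 * max(0.0, 1 - understory[q])
                new_adults[q] = min(rng.poisson(lam), preadults[q] + 2)
        else:  # mechanistic: pre-adults mature only while the stand is open
            site_canopy = canopy_per_quad.sum() / (config.light_capacity * n_quads)
            if stand_open and site_canopy > config.stand_close_at:
                stand_open = False
            elif not stand_open and site_canopy < config.stand_open_at:
                stand_open = True
            if stand_open:
                for q in range(n_quads):
                    if preadults[q] > 0:
                        light = max(0.0, 1 - canopy_per_quad[q] / config.light_capacity)
                        new_adults[q] = rng.binomial(preadults[q], config.maturation_prob * light)
                        preadults[q] -= new_adults[q]
        for q in range(n_quads):
            for _ in range(new_adults[q]):
                s0 = 4 + rng.poisson(1.5)
                mx = int(np.clip(np.exp(rng.normal(2.9, 0.4)), 6, 80))
                plants.append(_Plant(f"{site_id}-P{next_id:05d}", q, d, s0, mx, in_window))
                next_id += 1

        # --- adult survival over the coming quarter (hazard applied per census step) ---
        log_h = (np.log(config.baseline_hazard)
                 + config.temp_coef * anom_q[qi] * depth_factor
                 + config.wave_coef * float(storm_q[qi])
                 + config.urchin_coef * psu_series[qi])
        h = np.exp(log_h)
        for p in plants:
            if not p.alive:
                continue
            age = d - p.recruit_date
            hz = h + (config.thinning_hazard if age < 1.0 else 0.0)
            # stipe trajectory: saturating growth then senescence
            frac = age / (age + 0.6)
            sen = 1.0 if age < 3.0 else max(0.3, 1.0 - 0.12 * (age - 3.0))
            target = max(4, p.max_target * frac * sen)
            p.stipes = max(4, int(round(target * np.exp(rng.normal(0, 0.12)))))
            p.series.append((d, p.stipes))
            if rng.random() < 1.0 - np.exp(-hz * config.cadence):
                p.alive = False

        # --- juveniles, pre-adults, understory ---
        recent_disturb = any(0 <= d - td_ < 1.0 for td_ in disturb_times)
        for q in range(n_quads):
            light = max(0.0, 1 - canopy_per_quad[q] / config.light_capacity)
            space = max(0.0, 1 - understory[q])
            graze = max(0.0, 1 - 0.2 * psu_series[qi])
            lam = config.recruit_rate * light * space * graze
            if config.regime == "planted" and in_window is None:
                lam *= 0.1
            juveniles[q] = rng.poisson(lam) + int(juveniles[q] * 0.3)
            promoted = rng.binomial(juveniles[q], 0.25)
            juveniles[q] -= promoted
            preadults[q] = promoted + int(preadults[q] * 0.4)
            canopy_frac = canopy_per_quad[q] / config.light_capacity
            du = (config.understory_rate * understory[q] * (1 - understory[q]) * max(0.0, 1 - canopy_frac)
                  - config.understory_decay * understory[q] * canopy_frac) * config.cadence
            understory[q] = float(np.clip(understory[q] + du + rng.normal(0, 0.01), 0.01, 0.95))
            if storm_q[qi]:
                understory[q] *= 0.3
            desmarestia_pool[q] = (8.0 if (recent_disturb or storm_q[qi]) else desmarestia_pool[q] * 0.5)

        # --- census emission ---
        for q, (tr, qq) in enumerate(quad_keys):
            adults_here = [p for p in plants if p.alive and p.quadrat == q]
            u = understory[q]
            census_rows.append({
                "site_id": site_id, "transect_id": tr, "quadrat_id": qq, "date": d,
                "macro_adult": len(adults_here),
                "macro_preadult": preadults[q],
                "macro_juvenile": juveniles[q],
                "stipe_count": int(sum(p.stipes for p in adults_here)),
                "stipitate": rng.poisson(6.0 * u),
                "laminate": rng.poisson(4.0 * u),
                "desmarestia": rng.poisson(desmarestia_pool[q]),
                "brown_turf": float(np.clip(0.55 * u + rng.normal(0, 0.02), 0, 1)),
                "red_turf": float(np.clip(0.30 * u + rng.normal(0, 0.02), 0, 1)),
                "articulated_coralline": float(np.clip(0.20 * u + rng.normal(0, 0.02), 0, 1)),
                "cystoseira": float(np.clip(0.10 * u + rng.normal(0, 0.01), 0, 1)),
                "psu_density": float(psu_series[qi]),
                "rsu_density": float(rsu_series[qi]),
            })
        canopy_tl.append((d, canopy_per_quad.mean()))
        under_tl.append((d, understory.mean()))

    census = pd.DataFrame(census_rows)
    final_date = dates[-1]
    records = []
    memberships = {}
    for p in plants:
        if not p.series:
            continue
        rec = PlantRecord(
            plant_id=p.pid, site_id=site_id, quadrat_id=str(p.quadrat + 1),
            recruit_date=p.series[0][0], last_date=p.series[-1][0],
            dead=p.series[-1][0] < final_date - 1e-9,  # seen at final census => censored
            stipe_series=p.series,
        )
        records.append(rec)
        if p.window is not None:
            memberships[p.pid] = p.window

    pulsed_labels = []
    for a, b in windows:
        pulsed_labels.append("pulsed" if b - a <= 1.0 + 1e-9 else "trickled")
    truth = GroundTruth(
        windows=windows,
        memberships=memberships,
        pulsed_labels=pulsed_labels,
        effects={"temp_coef": config.temp_coef, "wave_coef": config.wave_coef,
                 "urchin_coef": config.urchin_coef},
        canopy=pd.DataFrame(canopy_tl, columns=["date", "mean_adults"]),
        understory=pd.DataFrame(under_tl, columns=["date", "mean_cover"]),
    )
    return census, records, truth


# ---------------------------------------------------------------------------
# generative cohort tables (for model-recovery checks)
# ---------------------------------------------------------------------------

def simulate_cohort_table(
    n_cohorts: int = 150,
    seed: int = 0,
    ad_coef: float = 0.02,
    understory_coef: float = -1.5,
    temp_coef: float = -0.35,
    wave_sill: tuple[float, float] = (4000.0, 6800.0),
    psu_coef: float = -0.15,
    rsu_coef: float = -0.5,
    decade_effects: dict[str, float] | None = None,
    nb_alpha: float = 0.15,
) -> pd.DataFrame:
    """Cohort-parameter table drawn from the additive models' own generative form.

    Cohort size N ~ NegBin(mean = exp(a0 + ad_coef*Ad + understory_coef*U +
    decade effect)); mean lifespan (days) ~ NegBin with a linear temperature
    effect, a rise-plateau-decline wave response (rise to ``wave_sill[0]``,
    plateau, decline past ``wave_sill[1]``), and linear urchin effects.  Used
    to check that the fitted smooths recover planted shapes and signs.
    """
    rng = np.random.default_rng(seed)
    onset = rng.uniform(1983, 2023, n_cohorts)
    decade = np.array([f"{int(t) // 10 * 10}s" for t in onset])
    de = decade_effects or {}
    ad = rng.poisson(25, n_cohorts).astype(float)
    understory = rng.uniform(0, 1.5, n_cohorts)
    temp80 = rng.uniform(13, 20, n_cohorts)
    wave80 = rng.uniform(500, 9500, n_cohorts)
    psu = rng.gamma(2.0, 0.8, n_cohorts)
    rsu = rng.gamma(2.0, 0.08, n_cohorts)

    eta_n = 3.0 + ad_coef * ad + understory_coef * understory \
        + np.array([de.get(d, 0.0) for d in decade])
    mu_n = np.exp(eta_n)
    N = rng.negative_binomial(1 / nb_alpha, 1 / (1 + nb_alpha * mu_n)) + 1

    lo, hi = wave_sill
    wave_part = np.where(wave80 < lo, 0.8 * (wave80 / lo - 1.0),
                         np.where(wave80 > hi, -1.2 * (wave80 - hi) / (9500 - hi), 0.0))
    eta_l = 5.8 + temp_coef * (temp80 - 16.0) + wave_part + psu_coef * psu + rsu_coef * rsu \
        + np.array([de.get(d, 0.0) for d in decade])
    mu_l = np.exp(eta_l)
    days = rng.negative_binomial(1 / nb_alpha, 1 / (1 + nb_alpha * mu_l)) + 1

    singles = rng.binomial(N, 0.3)
    pulsed = np.where(rng.random(n_cohorts) < 0.65, "pulsed", "trickled")
    return pd.DataFrame({
        "cohort_id": [f"SIM-{i + 1}" for i in range(n_cohorts)],
        "onset_date": onset, "decade": decade,
        "N": N, "singles": singles, "PA": rng.poisson(10, n_cohorts),
        "Ad": ad, "understory_1yr": understory,
        "life_mn": days / 365.25, "st_max_mn": rng.uniform(8, 40, n_cohorts),
        "temp80": temp80, "wave80": wave80,
        "psu_density": psu, "rsu_density": rsu,
        "pulsed": pulsed, "alive": False,
    })


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("two_pulses", "censored_tail")


def _fixture_two_pulses():
    """Two cohorts at one site over 10 years: the first pulsed, the second
    trickled by construction (recruitment spread over 1.5 years with less
    than 80% in the first year)."""
    site = "FIX"
    final = 2009.75
    plants = []
    # cohort 1: 10 plants, all recruiting 2000.00-2000.50, dying 2002-2003
    for i in range(10):
        rec = 2000.0 + 0.25 * (i % 3)
        last = 2002.0 + 0.25 * (i % 4)
        series = [(round(t, 2), 4 + int(2 * np.sin(j) + j)) for j, t in
                  enumerate(np.arange(rec, last + 1e-9, 0.25))]
        plants.append(PlantRecord(f"{site}-A{i:02d}", site, "1", rec, last, True, series))
    # cohort 2: 10 plants spread 2005.00-2006.50 (7 of 10 in the first year)
    recs = [2005.0, 2005.0, 2005.25, 2005.5, 2005.5, 2005.75, 2006.0, 2006.25, 2006.5, 2006.5]
    for i, rec in enumerate(recs):
        last = min(rec + 1.0 + 0.25 * i, final)
        series = [(round(t, 2), 5 + j) for j, t in enumerate(np.arange(rec, last + 1e-9, 0.25))]
        plants.append(PlantRecord(f"{site}-B{i:02d}", site, "2", rec, last,
                                  last < final - 1e-9, series))
    return {"plants": plants, "site_final": final,
            "expected": {"n_windows": 2, "labels": ["pulsed", "trickled"]}}


def _fixture_censored_tail():
    """Five plants alive at the series end (right-censored) plus five deaths."""
    site = "FIX"
    final = 2005.0
    plants = []
    for i in range(5):
        rec = 2000.0 + 0.25 * i
        series = [(round(t, 2), 6) for t in np.arange(rec, final + 1e-9, 0.25)]
        plants.append(PlantRecord(f"{site}-C{i:02d}", site, "1", rec, final, False, series))
    for i in range(5):
        rec, last = 2000.0, 2001.0 + 0.25 * i
        series = [(round(t, 2), 5) for t in np.arange(rec, last + 1e-9, 0.25)]
        plants.append(PlantRecord(f"{site}-D{i:02d}", site, "1", rec, last, True, series))
    return {"plants": plants, "site_final": final, "expected": {"n_censored": 5}}


def make_fixture(name: str) -> dict:
    """Deterministic tiny canned datasets with hand-checkable structure."""
    if name == "two_pulses":
        return _fixture_two_pulses()
    if name == "censored_tail":
        return _fixture_censored_tail()
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
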