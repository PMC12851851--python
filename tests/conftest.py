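import numpy as np
import pandas as pd
import pytest

from kelpcohorts.core_data import PlantRecord
from kelpcohorts.simulate import SimulationConfig, simulate_forcing, simulate_site


def make_census_frame(rows):
    """Build a census frame from short dicts, defaulting all other fields to 0."""
    defaults = {
        "macro_adult": 0, "macro_preadult": 0, "macro_juvenile": 0, "stipe_count": 0,
        "stipitate": 0, "laminate": 0, "desmarestia": 0,
        "brown_turf": 0.0, "red_turf": 0.0, "articulated_coralline": 0.0, "cystoseira": 0.0,
        "psu_density": 0.0, "rsu_density": 0.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def simple_plant(pid="p1", site="S", recruit=2000.0, last=2001.0, dead=True, stipes=None):
    dates = np.round(np.arange(recruit, last + 1e-9, 0.25), 4)
    if stipes is None:
        stipes = [5] * len(dates)
    return PlantRecord(pid, site, "1", recruit, last, dead,
                       list(zip(dates.tolist(), stipes)))


@pytest.fixture(scope="session")
def planted_site():
    """One simulated site with known pulse windows and memberships."""
    cfg = SimulationConfig(seed=11, n_sites=1, years=14, regime="planted", n_pulses=4)
    forcing = simulate_forcing(cfg)
    census, plants, truth = simulate_site(cfg, 0, forcing=forcing)
    return {"config": cfg, "census": census, "plants": plants, "truth": truth,
            "forcing": forcing}


@pytest.fixture(scope="session")
def small_disturbance_run():
    """Two mechanistic sites over 25 years with shared forcing."""
    cfg = SimulationConfig(seed=5, n_sites=2, years=25)
    forcing = simulate_forcing(cfg)
    out = []
    for i in range(2):
        out.append(simulate_site(cfg, i, forcing=forcing))
    return {"config": cfg, "sites": out, "forcing": forcing}
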