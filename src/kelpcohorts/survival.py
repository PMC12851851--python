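"""Product-limit (Kaplan-Meier) survivorship with right-censoring.

The estimator is the standard product over distinct event times

    S(t) = prod_{t_i <= t} (1 - d_i / n_i),

with censored durations leaving the risk set after their time (events
precede censorings at tied times).  Quantiles use the convention
q(p) = smallest event time t with S(t) <= 1 - p; if S never drops that low
the quantile is undefined and reported as NaN.

Fitting is delegated to ``lifelines.KaplanMeierFitter``; the curve is
re-exposed as a light :class:`SurvivalCurve` carrying event times, survival
probabilities, risk-set and event counts, and censoring times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["SurvivalCurve", "km_fit", "km_quantile", "pooled_site_curves"]


@dataclass
class SurvivalCurve:
    times: np.ndarray          # distinct event times, sorted
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n_i at each event time
    events: np.ndarray         # d_i at each event time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n: int = 0

    def s(self, t: float) -> float:
        """Step-function evaluation of S at time t (S = 1 before the first event)."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "n_risk": self.at_risk, "n_event": self.events}
        )

    def plot(self, ax=None, label=None, **kwargs):
        """Step plot of the survivor function."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label, **kwargs)
        ax.set_xlabel("years since adult recruitment")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.02)
        return ax


def km_fit(durations, events) -> SurvivalCurve:
    """Product-limit estimate from durations (years) and event flags (True = death)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty input")
    if durations.shape != events.shape:
        raise ValueError("durations and events must have the same length")
    if (durations < 0).any():
        raise ValueError("negative duration")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = np.array([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(int),
        events=ev["observed"].to_numpy(int),
        censor_times=np.sort(durations[~events]),
        n=len(durations),
    )


def km_quantile(curve: SurvivalCurve, p: float) -> float:
    """Survival time at probability p: smallest event time with S(t) <= 1 - p.

    Returns NaN (undefined) when the curve never drops to 1 - p.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    below = curve.survival <= (1.0 - p) + 1e-12
    if not below.any():
        return float("nan")
    return float(curve.times[np.argmax(below)])


def pooled_site_curves(plant_frame: pd.DataFrame, grouping: str = "site_id") -> dict:
    """One Kaplan-Meier curve per group (site or cohort), empty groups omitted.

    ``plant_frame`` needs ``duration``, ``event`` and the grouping column
    (see :func:`kelpcohorts.core_data.add_lifespans`).
    """
    curves = {}
    for key, grp in plant_frame.groupby(grouping):
        if len(grp) == 0:
            continue
        curves[key] = km_fit(grp["duration"].to_numpy(), grp["event"].to_numpy())
    return curves
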