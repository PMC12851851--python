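"""Guild pooling, scaling, five-state clustering of quadrat censuses, and state-shift detection.

Each quadrat-census is reduced to a nine-feature canopy-guild vector:
giant-kelp adults, stipe counts, juveniles (juvenile + pre-adult life stages
pooled), stipitate kelps, laminate kelps, brown turf (Dictyotales plus
*Cystoseira osmundacea*), red turf, articulated corallines, and the early
successional *Desmarestia ligulata*.  Features are z-scored over all
quadrat-censuses pooled across sites and times (sample sd, ``ddof=1``),
then clustered with CLARA k-medoids under Manhattan distance.  The
five-cluster solution is labeled Kelp / Disturbed / Recovery / Mixed /
Understory by deterministic rules on the medoid feature values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cluster import clara, gap_statistic  # noqa: F401  (re-exported for the pipeline)

__all__ = [
    "GUILD_FEATURES",
    "STATE_LABELS",
    "pool_guilds",
    "scale_features",
    "apply_scaling",
    "cluster_states",
    "label_states",
    "state_timeline",
    "detect_state_shifts",
]

GUILD_FEATURES = (
    "macro_adult",
    "stipe_count",
    "macro_juvenile",
    "stipitate",
    "laminate",
    "brown_turf",
    "red_turf",
    "articulated_coralline",
    "desmarestia",
)

STATE_LABELS = ("Kelp", "Disturbed", "Recovery", "Mixed", "Understory")

KEY = ["site_id", "transect_id", "quadrat_id", "date"]


def pool_guilds(census: pd.DataFrame) -> pd.DataFrame:
    """Nine unscaled guild features per quadrat-census.

    Juveniles pool all life stages prior to adulthood (juvenile + pre-adult
    counts); *Cystoseira* cover is pooled into brown turf while remaining a
    separate census column.
    """
    required = set(KEY) | {
        "macro_adult", "macro_preadult", "macro_juvenile", "stipe_count",
        "stipitate", "laminate", "brown_turf", "red_turf",
        "articulated_coralline", "cystoseira", "desmarestia",
    }
    missing = required - set(census.columns)
    if missing:
        raise ValueError(f"census table missing guild components: {sorted(missing)}")
    out = census[KEY].copy()
    out["macro_adult"] = census["macro_adult"]
    out["stipe_count"] = census["stipe_count"]
    out["macro_juvenile"] = census["macro_juvenile"] + census["macro_preadult"]
    out["stipitate"] = census["stipitate"]
    out["laminate"] = census["laminate"]
    out["brown_turf"] = census["brown_turf"] + census["cystoseira"]
    out["red_turf"] = census["red_turf"]
    out["articulated_coralline"] = census["articulated_coralline"]
    out["desmarestia"] = census["desmarestia"]
    return out


def scale_features(vectors: pd.DataFrame, method: str = "zscore") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize guild features; returns (scaled frame, scaling-parameter frame).

    ``zscore`` centers to mean 0, sd 1 (sample sd, n-1 denominator);
    ``range`` rescales to [0, 1].  Zero-variance features are set to 0 and a
    warning is issued.  The returned parameters reproduce the transform on
    new data via :func:`apply_scaling`.
    """
    scaled = vectors.copy()
    rows = []
    for col in GUILD_FEATURES:
        x = vectors[col].to_numpy(float)
        if method == "zscore":
            loc, span = np.mean(x), np.std(x, ddof=1) if len(x) > 1 else 0.0
        elif method == "range":
            loc, span = np.min(x), np.max(x) - np.min(x)
        else:
            raise ValueError(f"unknown scaling method {method!r}")
        if span == 0 or not np.isfinite(span):
            warnings.warn(f"feature '{col}' has zero variance; scaled to 0")
            scaled[col] = 0.0
            rows.append((col, loc, 0.0))
        else:
            scaled[col] = (x - loc) / span
            rows.append((col, loc, span))
    params = pd.DataFrame(rows, columns=["feature", "loc", "scale"])
    params.attrs["method"] = method
    return scaled, params


def apply_scaling(vectors: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Apply stored scaling parameters to new guild vectors (training-scale transform)."""
    out = vectors.copy()
    for _, row in params.iterrows():
        col = row["feature"]
        if row["scale"] == 0:
            out[col] = 0.0
        else:
            out[col] = (vectors[col] - row["loc"]) / row["scale"]
    return out


def cluster_states(
    scaled: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_samples: int = 5,
    sample_size: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CLARA k-medoids (Manhattan) on scaled guild vectors.

    Returns (assignments frame with a ``cluster`` column, medoid feature frame).
    """
    X = scaled[list(GUILD_FEATURES)].to_numpy(float)
    if k < 2:
        raise ValueError("k must be >= 2")
    res = clara(X, k, seed=seed, n_samples=n_samples, sample_size=sample_size)
    assignments = scaled[KEY].copy()
    assignments["cluster"] = res.labels + 1  # 1-based cluster ids
    medoids = pd.DataFrame(res.medoids, columns=list(GUILD_FEATURES))
    medoids.insert(0, "cluster", np.arange(1, k + 1))
    medoids.attrs["cost"] = res.cost
    return assignments, medoids


def label_states(medoids: pd.DataFrame, k: int = 5) -> dict[int, str]:
    """Map the five medoids onto {Kelp, Disturbed, Recovery, Mixed, Understory}.

    Deterministic priority rules on medoid features: the medoid with the
    largest adult+stipe score is Kelp; among the rest, largest juvenile score
    is Recovery; then largest *Desmarestia* score is Disturbed; of the final
    two, the one with the larger pooled understory score (stipitate +
    laminate + turfs + corallines) is Understory and the remainder Mixed.
    Exact ties are reported as a labeling failure.
    """
    if k != 5 or len(medoids) != 5:
        raise ValueError("state labeling is defined only for the five-cluster solution")
    m = medoids.set_index("cluster")
    remaining = list(m.index)

    def _take(score: pd.Series, label: str) -> int:
        sub = score.loc[remaining]
        top = sub.max()
        winners = list(sub.index[sub == top])
        if len(winners) > 1:
            # identical medoids cannot be told apart at all -> labeling fails
            if any(m.loc[a].equals(m.loc[b]) for a in winners for b in winners if a != b):
                raise ValueError(f"state labeling tie for {label!r}: identical medoids {winners}")
            # score tie between distinct medoids: the less kelp-like one wins
            kelpiness = (m["macro_adult"] + m["stipe_count"]).loc[winners]
            winners = [int(kelpiness.idxmin())]
        c = int(winners[0])
        remaining.remove(c)
        return c

    labels: dict[int, str] = {}
    labels[_take(m["macro_adult"] + m["stipe_count"], "Kelp")] = "Kelp"
    labels[_take(m["macro_juvenile"], "Recovery")] = "Recovery"
    labels[_take(m["desmarestia"], "Disturbed")] = "Disturbed"
    understory_score = (
        m["stipitate"] + m["laminate"] + m["brown_turf"] + m["red_turf"] + m["articulated_coralline"]
    )
    labels[_take(understory_score, "Understory")] = "Understory"
    labels[remaining[0]] = "Mixed"
    if len(set(labels.values())) != 5:
        raise ValueError("state labeling failed to produce a bijection")
    return labels


def state_timeline(assignments: pd.DataFrame, labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Fraction of quadrats in each state per site and census date.

    Missing quadrats are excluded from the denominator; fractions sum to 1 at
    every site-date.
    """
    df = assignments.copy()
    if labels is not None:
        df["state"] = df["cluster"].map(labels)
        states = [s for s in STATE_LABELS if s in set(df["state"])]
    else:
        df["state"] = df["cluster"].astype(str)
        states = sorted(df["state"].unique())
    counts = (
        df.groupby(["site_id", "date", "state"]).size().unstack("state", fill_value=0)
    )
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac = frac.reindex(columns=states, fill_value=0.0)
    return frac.reset_index()


def detect_state_shifts(
    timeline: pd.DataFrame,
    dominance_threshold: float = 0.4,
    persistence: float = 1.0,
) -> pd.DataFrame:
    """Persistent dominant-state changes per site.

    A site is "in" state S at a census when S has the maximum fraction and
    that fraction is >= ``dominance_threshold``.  A run of consecutive
    censuses in the same state is *established* when it spans at least
    ``persistence`` years (run duration includes one census interval).  A
    shift event is emitted when the established state changes.
    """
    state_cols = [c for c in timeline.columns if c not in ("site_id", "date")]
    events = []
    for site, grp in timeline.groupby("site_id"):
        grp = grp.sort_values("date")
        dates = grp["date"].to_numpy(float)
        if len(dates) > 1:
            cadence = float(np.median(np.diff(dates)))
        else:
            cadence = 0.25
        frac = grp[state_cols].to_numpy(float)
        dom = []
        for row in frac:
            i = int(np.argmax(row))
            dom.append(state_cols[i] if row[i] >= dominance_threshold else None)
        # collapse into runs
        runs = []  # (state, start, end)
        for d, s in zip(dates, dom):
            if runs and runs[-1][0] == s:
                runs[-1][2] = d
            else:
                runs.append([s, d, d])
        established = [
            (s, a, b) for s, a, b in runs
            if s is not None and (b - a) + cadence >= persistence - 1e-9
        ]
        for (s0, _, _), (s1, a1, _) in zip(established, established[1:]):
            if s1 != s0:
                events.append((site, s0, s1, a1))
    return pd.DataFrame(events, columns=["site_id", "from_state", "to_state", "date"])
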