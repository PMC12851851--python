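"""k-medoids clustering (PAM build + swap) with a CLARA subsampling wrapper,
Manhattan distance throughout, and the gap statistic for choosing k.

PAM (partitioning around medoids) is run exactly on subsamples; CLARA draws
``n_samples`` subsamples of size ``sample_size`` (default ``40 + 2k``, the
classic recommendation), runs PAM on each, and keeps the medoid set that
minimizes the total Manhattan distance of *all* points to their nearest
medoid.  When the dataset is no larger than the subsample size CLARA
degenerates to a single exact PAM run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KMedoidsResult", "pam", "clara", "gap_statistic"]


@dataclass
class KMedoidsResult:
    medoid_indices: np.ndarray  # indices into the full data set
    labels: np.ndarray          # cluster index per point, 0..k-1
    cost: float                 # total Manhattan distance to assigned medoids
    medoids: np.ndarray         # medoid coordinate rows


def _assign(X: np.ndarray, medoid_idx: np.ndarray) -> tuple[np.ndarray, float]:
    d = cdist(X, X[medoid_idx], metric="cityblock")
    labels = np.argmin(d, axis=1)
    return labels, float(d[np.arange(len(X)), labels].sum())


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    dist_near = D[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate j: sum of reductions in nearest-medoid distance
        gains = np.maximum(dist_near[:, None] - D, 0).sum(axis=0)
        gains[medoids] = -1.0
        j = int(np.argmax(gains))
        medoids.append(j)
        dist_near = np.minimum(dist_near, D[:, j])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        sub = D[:, medoids]
        nearest = sub.min(axis=1)
        cost = nearest.sum()
        best_delta, best_swap = 0.0, None
        for mi in range(len(medoids)):
            others = np.delete(sub, mi, axis=1)
            second = others.min(axis=1) if others.size else np.full(n, np.inf)
            served = (sub[:, mi] <= nearest + 1e-12)[:, None]
            # swap deltas for every candidate h at once (columns of D)
            newd = np.where(served, np.minimum(second[:, None], D),
                            np.minimum(nearest[:, None], D))
            deltas = newd.sum(axis=0) - cost
            deltas[medoids] = np.inf
            h = int(np.argmin(deltas))
            if deltas[h] < best_delta - 1e-12:
                best_delta, best_swap = deltas[h], (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
    return medoids


def pam(X: np.ndarray, k: int, rng: np.random.Generator | None = None, n_restarts: int | None = None) -> KMedoidsResult:
    """Exact PAM (build + swap to a local optimum) with Manhattan distance.

    Besides the deterministic BUILD initialization, ``n_restarts`` extra
    random initializations are swapped to local optima and the best kept,
    which in practice reaches the global optimum on small instances.  The
    default is 12 restarts for tiny instances (n <= 20), 2 otherwise.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n_restarts is None:
        n_restarts = 12 if n <= 20 else 2
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature value")
    D = cdist(X, X, metric="cityblock")
    inits = [_pam_build(D, k)]
    if rng is not None:
        for _ in range(n_restarts):
            inits.append(list(rng.choice(n, size=k, replace=False)))
    best = None
    for init in inits:
        med = _pam_swap(D, init)
        cost = D[:, med].min(axis=1).sum()
        if best is None or cost < best[1] - 1e-12:
            best = (med, cost)
    med_idx = np.array(sorted(best[0]))
    labels, cost = _assign(X, med_idx)
    return KMedoidsResult(med_idx, labels, cost, X[med_idx])


def clara(
    X: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_samples: int = 5,
    sample_size: int | None = None,
) -> KMedoidsResult:
    """CLARA k-medoids: PAM on subsamples, evaluated on the full data set.

    Each subsample after the first also includes the current best medoids
    (the classic refinement).  Identical seed gives identical output.
    """
    X = np.asarray(X, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(X)
    if sample_size is None:
        sample_size = 40 + 2 * k
    sample_size = min(n, sample_size)
    if n <= sample_size:
        return pam(X, k, rng=rng)
    best: KMedoidsResult | None = None
    for _ in range(n_samples):
        pool = np.arange(n)
        if best is not None:
            forced = best.medoid_indices
            rest = rng.choice(np.setdiff1d(pool, forced), size=sample_size - k, replace=False)
            sub = np.concatenate([forced, rest])
        else:
            sub = rng.choice(pool, size=sample_size, replace=False)
        sub_res = pam(X[sub], k, rng=rng)
        med_idx = sub[sub_res.medoid_indices]
        labels, cost = _assign(X, med_idx)
        if best is None or cost < best.cost - 1e-12:
            best = KMedoidsResult(np.sort(med_idx), labels, cost, X[np.sort(med_idx)])
    labels, cost = _assign(X, best.medoid_indices)
    return KMedoidsResult(best.medoid_indices, labels, cost, X[best.medoid_indices])


def _within_dispersion(X: np.ndarray, k: int, rng: np.random.Generator) -> float:
    if k == 1:
        D = cdist(X, X, metric="cityblock")
        return float(D.sum(axis=0).min())
    res = clara(X, k, seed=rng, n_samples=2)
    return max(res.cost, 1e-12)


def gap_statistic(
    X: np.ndarray,
    k_max: int,
    B: int = 20,
    seed: int = 0,
) -> tuple[int, "np.ndarray", "np.ndarray"]:
    """Gap statistic over k = 1..k_max with a uniform reference over per-feature ranges.

    gap(k) = mean_b log W*_kb - log W_k, with W_k the total within-cluster
    Manhattan distance to medoids.  The optimal k is the smallest k with
    gap(k) >= gap(k+1) - s(k+1) (one-standard-error rule), where
    s(k) = sd_b(log W*_kb) * sqrt(1 + 1/B).

    Returns (k_opt, gap curve of length k_max, s curve).
    """
    X = np.asarray(X, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array([np.log(_within_dispersion(X, k, rng)) for k in range(1, k_max + 1)])
    ref_log_w = np.empty((B, k_max))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        for k in range(1, k_max + 1):
            ref_log_w[b, k - 1] = np.log(_within_dispersion(Xb, k, rng))
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=1) * np.sqrt(1 + 1 / B)
    k_opt = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            k_opt = k
            break
    return k_opt, gap, s
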