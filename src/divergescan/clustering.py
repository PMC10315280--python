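"""Divergence-profile clustering: fuzzy c-means and k-means.

Per-gene profiles are the eight genotype x stage cell means of normalized
expression, z-scored per gene. The number of fuzzy clusters is chosen from
the minimum centroid distance (Dmin) curve: excess clusters produce nearly
coincident centroids, so Dmin collapses once c exceeds the number of real
groups. The selection rule takes the largest c before Dmin first drops
below a configurable fraction of its c = 2 value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import GENOTYPES, STAGES_EXPR
from .errors import DivergescanError


def standardize_profiles(normalized: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scored genotype x stage cell-mean profiles.

    Columns are ordered HAL2-D1..D4 then FIL2-D1..D4. Genes whose cell means
    are constant (zero variance) are dropped.
    """
    cells = []
    for g in GENOTYPES:
        for s in STAGES_EXPR:
            samples = design.loc[
                (design["genotype"] == g) & (design["stage"] == s), "sample"
            ].tolist()
            cells.append(normalized[samples].mean(axis=1).rename(f"{g}_{s}"))
    prof = pd.concat(cells, axis=1)
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    keep = sd > 0
    return prof.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def mfuzz_fuzzifier(n: int, d: int) -> float:
    """Data-driven fuzzifier m, following the Mfuzz heuristic.

    Depends on the number of profiles n and their dimensionality d; always
    > 1.
    """
    return float(
        1.0
        + (1418.0 / n + 22.05) * d ** (-2.0)
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


@dataclass
class FuzzyCMeansResult:
    centroids: np.ndarray  # c x d
    membership: np.ndarray  # n x c, rows sum to 1
    objective: float
    n_iter: int
    converged: bool


def fuzzy_cmeans(
    profiles: np.ndarray | pd.DataFrame,
    c: int,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
) -> FuzzyCMeansResult:
    """Standard fuzzy c-means on Euclidean distance, best of ``n_init`` starts.

    Each start initializes centroids from ``c`` distinct profiles chosen by
    the seeded generator; iteration alternates membership and centroid
    updates until the objective changes by less than ``tol``. The restart
    with the lowest final objective is returned (a single random start can
    leave two initial centroids in one true group and converge there).
    """
    rng = np.random.default_rng(seed)
    best: FuzzyCMeansResult | None = None
    for _ in range(max(n_init, 1)):
        res = _fuzzy_cmeans_once(profiles, c, m, rng, tol, max_iter)
        if best is None or res.objective < best.objective:
            best = res
    return best


def _fuzzy_cmeans_once(profiles, c, m, rng, tol, max_iter) -> FuzzyCMeansResult:
    X = np.asarray(profiles, float)
    n, d = X.shape
    if c < 2:
        raise DivergescanError("fuzzy c-means needs c >= 2")
    if m is None:
        m = mfuzz_fuzzifier(n, d)
    if m <= 1:
        raise DivergescanError("fuzzifier m must be > 1")
    centroids = X[rng.choice(n, size=c, replace=False)].copy()
    obj_old = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        obj = float((um * d2).sum())
        if abs(obj_old - obj) < tol * (abs(obj) + 1.0):
            converged = True
            break
        obj_old = obj
    d2 = np.maximum(((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2), 1e-12)
    inv = d2 ** (-1.0 / (m - 1.0))
    u = inv / inv.sum(axis=1, keepdims=True)
    return FuzzyCMeansResult(centroids, u, float(((u ** m) * d2).sum()), it, converged)


def min_centroid_distance(centroids: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between centroids."""
    c = len(centroids)
    dmin = np.inf
    for i in range(c):
        for j in range(i + 1, c):
            dmin = min(dmin, float(np.linalg.norm(centroids[i] - centroids[j])))
    return dmin


def min_centroid_distance_curve(
    profiles: np.ndarray | pd.DataFrame,
    c_range=range(2, 13),
    m: float | None = None,
    seed: int = 0,
    rule: str = "drop",
    drop_frac: float = 1.0 / 3.0,
    floor_frac: float = 0.1,
) -> tuple[pd.DataFrame, int]:
    """Dmin for each candidate c, plus the selected cluster number.

    Once c exceeds the number of real groups, two centroids land in the same
    group and Dmin collapses. The default ``rule="drop"`` selects the c just
    before the first collapse — the first consecutive step where Dmin falls
    below ``drop_frac`` of its previous value (falling back to the largest
    proportional drop when no step collapses). ``rule="floor"`` instead
    takes the largest c before Dmin first falls below ``floor_frac`` times
    its value at the smallest c (kept as an alternative; the absolute floor
    is sensitive to where the post-collapse plateau happens to sit). A
    single-value range returns that c.
    """
    X = np.asarray(profiles, float)
    c_values = sorted(set(int(c) for c in c_range))
    if len(X) < max(c_values):
        raise DivergescanError("more clusters requested than profiles available")
    rows = []
    for c in c_values:
        res = fuzzy_cmeans(X, c, m=m, seed=seed)
        rows.append({"c": c, "dmin": min_centroid_distance(res.centroids)})
    curve = pd.DataFrame(rows)
    if len(c_values) == 1:
        return curve, c_values[0]
    dmin = curve["dmin"].to_numpy()
    if rule == "drop":
        ratios = dmin[1:] / np.maximum(dmin[:-1], 1e-12)
        below = np.flatnonzero(ratios < drop_frac)
        i = int(below[0]) if below.size else int(np.argmin(ratios))
        selected = c_values[i]
    elif rule == "floor":
        floor = floor_frac * dmin[0]
        selected = c_values[-1]
        for i in range(1, len(c_values)):
            if dmin[i] < floor:
                selected = c_values[i - 1]
                break
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return curve, selected


def kmeans_cluster(
    profiles: np.ndarray | pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Hard k-means assignments with multiple restarts (best inertia kept)."""
    X = np.asarray(profiles, float)
    if k > len(X):
        raise DivergescanError(f"k={k} exceeds the number of profiles ({len(X)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)
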