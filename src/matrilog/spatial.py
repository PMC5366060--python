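"""Spatial clustering of multi-family logs and elevation comparisons.

The Cuzick-Edwards test asks whether case locations (here, MF logs) cluster
among a fixed set of sampled locations, by counting, over all cases, how many
of each case's k nearest neighbours are also cases (the statistic T_k).
Significance is assessed at the upper tail against a Monte-Carlo null built by
permuting case/control labels over the fixed locations; the test therefore
conditions on the actual sampling design and needs no background population
density.

Distances default to great-circle (haversine) on WGS84 degrees, appropriate
for a landscape spanning several US states; a planar Euclidean metric is
available for small extents.  Nearest-neighbour ties are broken by ascending
input index, which makes every result deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088

_PERM_CHUNK = 2000  # label permutations evaluated per vectorised block


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """All-pairs great-circle distance (km) between points given in degrees."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _distance_matrix(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "haversine":
        return haversine_matrix(points[:, 0], points[:, 1])
    if metric == "planar":
        d = points[:, None, :] - points[None, :, :]
        return np.sqrt((d**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


def knn_neighbors(points: Sequence[Sequence[float]], k: int, metric: str = "haversine") -> np.ndarray:
    """Indices of each point's k nearest other points, shape (n, k).

    Points are (lat, lon) pairs.  Self is excluded; exact distance ties are
    broken by ascending input index (stable sort), so coincident coordinates
    are allowed and handled deterministically.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least {k + 1} points, got {n}")
    dist = _distance_matrix(pts, metric)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def tk_statistic(case_labels: np.ndarray, neighbors: np.ndarray) -> int:
    """T_k: total count of case neighbours over all cases."""
    y = np.asarray(case_labels, dtype=bool)
    return int((y[:, None] & y[neighbors]).sum())


@dataclass
class CuzickEdwardsResult:
    """One Cuzick-Edwards test: statistic, Monte-Carlo null summary and p-values."""

    k: int
    t_obs: int
    n_reps: int
    p_raw: float
    p_bonferroni: float
    n_cases: int
    n_controls: int
    seed: int


def cuzick_edwards(
    points: Sequence[Sequence[float]],
    case_labels: Sequence[bool],
    k: int,
    n_reps: int = 9999,
    seed: int = 0,
    metric: str = "haversine",
    bonferroni_factor: int = 1,
) -> CuzickEdwardsResult:
    """Cuzick-Edwards T_k with a Monte-Carlo permutation null (upper tail).

    Labels are permuted over the fixed locations; the p-value uses the add-one
    convention p = (1 + #{T* >= T_obs}) / (n_reps + 1), so it can never be 0.
    """
    y = np.asarray(case_labels, dtype=bool)
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("Cuzick-Edwards test needs at least one case and one control")
    nbrs = knn_neighbors(points, k, metric=metric)
    t_obs = tk_statistic(y, nbrs)

    rng = np.random.default_rng(seed)
    exceed = 0
    remaining = n_reps
    while remaining > 0:
        m = min(_PERM_CHUNK, remaining)
        perms = rng.permuted(np.tile(y, (m, 1)), axis=1)
        nbr_counts = perms[:, nbrs].sum(axis=2)  # (m, n) case-neighbour counts
        t_null = (perms * nbr_counts).sum(axis=1)
        exceed += int((t_null >= t_obs).sum())
        remaining -= m
    p_raw = (1 + exceed) / (n_reps + 1)
    return CuzickEdwardsResult(
        k=k,
        t_obs=t_obs,
        n_reps=n_reps,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * bonferroni_factor),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


#: Control groups selectable against MF cases.
CONTROL_SCHEMES = {
    "omh": ("OMH",),
    "sh": ("SH",),
    "combined": ("SH", "OMH"),
}


def run_clustering_suite(
    class_table: pd.DataFrame,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    schemes: Sequence[str] = ("omh", "sh", "combined"),
    n_reps: int = 9999,
    seed: int = 0,
    metric: str = "haversine",
    global_correction: bool = False,
) -> pd.DataFrame:
    """Run the Cuzick-Edwards test for every control scheme and neighbourhood size.

    MF logs are cases.  The Bonferroni factor is the number of k values tested
    per scheme, or the full scheme x k grid when ``global_correction`` is set.
    Child RNG seeds are derived deterministically from ``seed``.
    """
    factor = len(k_values) * (len(schemes) if global_correction else 1)
    master = np.random.default_rng(seed)
    rows = []
    for scheme in schemes:
        controls = CONTROL_SCHEMES[scheme]
        subset = class_table[class_table["log_class"].isin(("MF",) + controls)]
        labels = (subset["log_class"] == "MF").to_numpy()
        points = subset[["latitude", "longitude"]].to_numpy(dtype=float)
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise ValueError(f"scheme {scheme!r}: fewer than 2 cases or 2 controls")
        for k in k_values:
            child_seed = int(master.integers(2**31))
            res = cuzick_edwards(
                points, labels, k, n_reps=n_reps, seed=child_seed, metric=metric,
                bonferroni_factor=factor,
            )
            rows.append(
                {
                    "scheme": scheme,
                    "k": k,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                    "t_obs": res.t_obs,
                    "n_reps": res.n_reps,
                    "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TwoSampleTestResult:
    """Pooled-variance two-sample t-test with its companion variance-ratio F-test."""

    t: float
    df: int
    p: float
    f_stat: float
    f_df: tuple[int, int]
    f_p: float
    n1: int
    n2: int


def two_sample_equal_variance_test(x: Sequence[float], y: Sequence[float]) -> TwoSampleTestResult:
    """Two-tailed pooled-variance t-test (df = n1+n2-2) plus a two-tailed F-test.

    The F statistic places the larger sample variance in the numerator; the
    F-test checks the equal-variance assumption underlying the pooled t.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va if va > 0 else np.inf, len(b) - 1, len(a) - 1
    f_p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    t_res = stats.ttest_ind(a, b, equal_var=True)
    return TwoSampleTestResult(
        t=float(t_res.statistic),
        df=len(a) + len(b) - 2,
        p=float(t_res.pvalue),
        f_stat=float(f),
        f_df=(dfn, dfd),
        f_p=f_p,
        n1=len(a),
        n2=len(b),
    )


def elevation_tests(
    class_table: pd.DataFrame,
    schemes: Sequence[str] = ("omh", "sh", "combined"),
) -> pd.DataFrame:
    """Compare mean elevation of MF logs against each control scheme.

    Logs with missing elevation are excluded with a warning.
    """
    tab = class_table
    if tab["elevation"].isna().any():
        n_missing = int(tab["elevation"].isna().sum())
        warnings.warn(f"excluding {n_missing} log(s) with missing elevation", stacklevel=2)
        tab = tab.dropna(subset=["elevation"])
    mf = tab.loc[tab["log_class"] == "MF", "elevation"].to_numpy(dtype=float)
    rows = []
    for scheme in schemes:
        ctrl = tab.loc[tab["log_class"].isin(CONTROL_SCHEMES[scheme]), "elevation"].to_numpy(dtype=float)
        res = two_sample_equal_variance_test(mf, ctrl)
        rows.append(
            {
                "scheme": scheme,
                "n_cases": res.n1,
                "n_controls": res.n2,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "f_stat": res.f_stat,
                "f_df1": res.f_df[0],
                "f_df2": res.f_df[1],
                "f_p": res.f_p,
            }
        )
    return pd.DataFrame(rows)
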