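"""Group structure statistics on distance matrices.

Covers within/between-group distance summaries, multivariate dispersion
(betadisper-style distances to group centroids in a principal-coordinates
embedding with the negative-eigenvalue correction), Mantel tests between
distance matrices, great-circle geographic distances, and isolation-by-
distance tests against log10-transformed physical distances in meters.

All permutation p-values use the observed-included (+1) convention,
p = (1 + #{stat_perm >= stat_obs}) / (1 + nperm), so the smallest attainable
p with 9999 permutations is exactly 0.0001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# within / between summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceSummary:
    groups_used: list[str]
    mean_within: float            # over all within-group pairs, NaN if none
    mean_within_per_group: dict[str, float]
    mean_between: float           # NaN (flagged) when < 2 retained groups
    n_within_pairs: int
    n_between_pairs: int


def _group_vector(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    if isinstance(groups, dict):
        return np.asarray([groups[s] for s in dm.ids])
    g = np.asarray(groups)
    if len(g) != dm.n:
        raise ValueError("group labels must cover all samples")
    return g


def within_between_summary(dm: DistanceMatrix, groups, min_size: int = 3) -> GroupDistanceSummary:
    """Mean within- and between-group distances over groups of >= min_size."""
    g = _group_vector(dm, groups)
    labels = [l for l in dict.fromkeys(g.tolist()) if (g == l).sum() >= min_size]
    keep = np.isin(g, labels)
    idx = np.flatnonzero(keep)
    v = dm.values
    within, between = [], []
    per_group: dict[str, list[float]] = {l: [] for l in labels}
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if g[i] == g[j]:
                within.append(v[i, j])
                per_group[g[i]].append(v[i, j])
            else:
                between.append(v[i, j])
    return GroupDistanceSummary(
        groups_used=[str(l) for l in labels],
        mean_within=float(np.mean(within)) if within else float("nan"),
        mean_within_per_group={
            str(l): (float(np.mean(d)) if d else float("nan")) for l, d in per_group.items()
        },
        mean_between=float(np.mean(between)) if len(labels) >= 2 and between else float("nan"),
        n_within_pairs=len(within),
        n_between_pairs=len(between),
    )


# ---------------------------------------------------------------------------
# principal-coordinates embedding and dispersion
# ---------------------------------------------------------------------------

def _pcoa_axes(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the double-centered squared-distance matrix.

    Returns real-axis coordinates (positive eigenvalues) and "imaginary"
    axis coordinates (negative eigenvalues), each scaled by sqrt(|lambda|).
    """
    n = dm.n
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    tol = max(abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    neg = evals < -tol
    x_pos = evecs[:, pos] * np.sqrt(evals[pos])
    x_neg = evecs[:, neg] * np.sqrt(-evals[neg])
    return x_pos, x_neg


def _centroid_distances(x_pos: np.ndarray, x_neg: np.ndarray, g: np.ndarray) -> np.ndarray:
    d2 = np.empty(len(g))
    for label in np.unique(g):
        sel = g == label
        cp = x_pos[sel].mean(axis=0)
        cn = x_neg[sel].mean(axis=0) if x_neg.size else np.zeros(0)
        dev_pos = ((x_pos[sel] - cp) ** 2).sum(axis=1)
        dev_neg = ((x_neg[sel] - cn) ** 2).sum(axis=1) if x_neg.size else 0.0
        d2[sel] = np.maximum(dev_pos - dev_neg, 0.0)
    return np.sqrt(d2)


def distances_to_centroid(dm: DistanceMatrix, groups) -> np.ndarray:
    """Per-sample distance to its group centroid in PCoA space.

    Squared centroid distance is the squared deviation summed over
    positive-eigenvalue axes minus the sum over negative-eigenvalue axes
    (the imaginary correction for non-Euclidean distance matrices), floored
    at zero before the square root. Treating all samples as one group gives
    distances to the overall centroid.
    """
    if dm.n < 3:
        raise ValueError("need at least three samples")
    g = _group_vector(dm, groups)
    x_pos, x_neg = _pcoa_axes(dm)
    return _centroid_distances(x_pos, x_neg, g)


@dataclass
class DispersionResult:
    centroid_distances: np.ndarray
    group_means: dict[str, float]
    f_stat: float
    p_value: float
    nperm: int
    seed: int | None


def dispersion_test(
    dm: DistanceMatrix, groups, nperm: int = 9999, seed: int | None = None
) -> DispersionResult:
    """Permutation test of homogeneity of group dispersions.

    F is the one-way ANOVA statistic on the per-sample centroid distances;
    the p-value permutes group labels (recomputing centroid distances each
    time) with the +1 convention.
    """
    g = _group_vector(dm, groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    x_pos, x_neg = _pcoa_axes(dm)

    def f_of(gv: np.ndarray) -> float:
        d = _centroid_distances(x_pos, x_neg, gv)
        groups_d = [d[gv == l] for l in np.unique(gv)]
        f, _ = stats.f_oneway(*groups_d)
        return float(f)

    f_obs = f_of(g)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(nperm):
        if f_of(rng.permutation(g)) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + nperm)
    d_obs = _centroid_distances(x_pos, x_neg, g)
    return DispersionResult(
        centroid_distances=d_obs,
        group_means={str(l): float(d_obs[g == l].mean()) for l in labels},
        f_stat=f_obs,
        p_value=p,
        nperm=nperm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel and isolation by distance
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    nperm: int
    seed: int | None


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, nperm: int = 9999, seed: int | None = None
) -> MantelResult:
    """One-sided (upper) Mantel test between two distance matrices.

    Pearson r over the off-diagonal upper triangles; rows and columns of the
    second matrix are permuted jointly; p uses the +1 convention, so the
    floor at 9999 permutations is exactly 0.0001.
    """
    if d1.ids != d2.ids:
        if set(d1.ids) != set(d2.ids):
            raise ValueError("matrices must cover the same samples")
        d2 = d2.reorder(d1.ids)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    a = d1.values[iu]
    b = d2.values[iu]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing-distance pairs present; resolve before the Mantel test")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")

    az = (a - a.mean()) / a.std()
    r_obs = float(np.mean(az * (b - b.mean()) / b.std()))
    rng = np.random.default_rng(seed)
    v2 = d2.values
    n_ge = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        bp = v2[np.ix_(perm, perm)][iu]
        r = float(np.mean(az * (bp - bp.mean()) / bp.std()))
        if r >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + nperm)
    return MantelResult(r=r_obs, p_value=p, nperm=nperm, seed=seed)


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371,000 m."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = math.sin((la2 - la1) / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def geo_distance_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (meters) from a sample metadata table.

    ``metadata`` needs columns sample, lat, lon with decimal-degree
    coordinates; out-of-range latitudes (a classic sign of swapped columns)
    fail loudly.
    """
    lat = metadata["lat"].to_numpy(dtype=float)
    lon = metadata["lon"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        bad = metadata.loc[(lat < -90) | (lat > 90), "sample"].tolist()
        raise ValueError(f"latitude outside [-90, 90] for samples {bad}")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude outside [-180, 180]")
    ids = metadata["sample"].astype(str).tolist()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_m(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(ids, d)


@dataclass
class IBDResult:
    mantel: MantelResult
    anova_f: float
    anova_p: float
    pearson_r: float
    n_pairs: int


def ibd_test(
    d_gen: DistanceMatrix,
    metadata: pd.DataFrame,
    nperm: int = 9999,
    seed: int | None = None,
    floor_m: float = 1.0,
    exclude_within_pond: bool = False,
) -> IBDResult:
    """Isolation by distance: genetic distance vs log10 physical distance.

    Physical pair distances in meters are floored at ``floor_m`` (co-located
    samples would otherwise produce log10(0)) and log10-transformed. Returns
    the Mantel test between the genetic and log-physical matrices plus an
    ordinary least-squares ANOVA of genetic on log-physical pair distances
    (pairs are not independent; the F test is the conventional companion
    statistic, not a substitute for the permutation test).
    """
    meta = metadata.set_index(metadata["sample"].astype(str)).loc[d_gen.ids].reset_index(drop=True)
    d_geo = geo_distance_matrix(meta)
    if np.all(d_geo.condensed() == 0):
        raise ValueError("all samples are co-located; no geographic signal to test")
    logd = np.log10(np.maximum(d_geo.values, floor_m))
    np.fill_diagonal(logd, 0.0)
    d_log = DistanceMatrix(d_gen.ids, logd)

    iu = np.triu_indices(d_gen.n, k=1)
    x = d_log.values[iu]
    y = d_gen.values[iu]
    if exclude_within_pond:
        keep = d_geo.values[iu] > 0
        x, y = x[keep], y[keep]
    res = stats.linregress(x, y)
    # anova(lm(y ~ x)): F = t^2 of the slope, same p
    f = float(res.rvalue**2 / (1 - res.rvalue**2) * (len(x) - 2)) if abs(res.rvalue) < 1 else float("inf")
    mantel = mantel_test(d_gen, d_log, nperm=nperm, seed=seed)
    return IBDResult(
        mantel=mantel,
        anova_f=f,
        anova_p=float(res.pvalue),
        pearson_r=float(res.rvalue),
        n_pairs=len(x),
    )
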