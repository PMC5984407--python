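"""Spatial structure statistics: Mantel test, Mantel correlogram, Hellinger
abundance distances and great-circle site distances."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model import DistanceMatrix, KleptopopError

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distance_matrix(sites: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) from a site table with columns
    ``site``, ``latitude``, ``longitude``."""
    labels = list(sites["site"])
    lat = sites["latitude"].to_numpy(float)
    lon = sites["longitude"].to_numpy(float)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(labels, values)


def _aligned_condensed(m1: DistanceMatrix, m2: DistanceMatrix):
    if m1.labels != m2.labels:
        if set(m1.labels) != set(m2.labels):
            raise KleptopopError("Mantel matrices have different labels")
        m2 = m2.submatrix(m1.labels)
    return m1.condensed(), m2, m1.labels


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation Mantel test between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal upper triangles;
    the one-tailed p-value is the proportion of row/column permutations of
    the second matrix with ``r_perm >= r``, counting the observed matrix
    itself (so p is never 0).
    """
    v1, m2a, _ = _aligned_condensed(m1, m2)
    full2 = m2a.values
    v2 = m2a.condensed()
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise KleptopopError("Mantel correlation undefined for a constant matrix")
    r = float(np.corrcoef(v1, v2)[0, 1])
    n = len(m1.labels)
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    z1 = (v1 - v1.mean()) / v1.std()
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = full2[np.ix_(perm, perm)][iu]
        rp = float(np.mean(z1 * (vp - vp.mean()) / vp.std()))
        if rp >= r - 1e-12:
            count += 1
    p = count / (n_perm + 1)
    return {"r": r, "r_squared": r * r, "p": p}


def mantel_correlogram(
    m_gen: DistanceMatrix,
    m_geo: DistanceMatrix,
    n_classes: int = 20,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram over equal-width geographic distance classes.

    For each class the statistic is the Mantel correlation between the
    genetic matrix and the class-membership indicator, with the sign flipped
    so that positive values mean that pairs within the class are more similar
    than average (positive spatial autocorrelation).  One-tailed permutation
    p-values are corrected progressively (Holm's correction over the classes
    tested so far).  Empty classes are reported with NaN.
    """
    v_gen, m_geo_a, _ = _aligned_condensed(m_gen, m_geo)
    v_geo = m_geo_a.condensed()
    n = len(m_gen.labels)
    iu = np.triu_indices(n, k=1)
    lo, hi = v_geo.min(), v_geo.max()
    if hi <= lo:
        raise KleptopopError("geographic distances are constant")
    width = (hi - lo) / n_classes
    edges = lo + width * np.arange(n_classes + 1)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_classes):
        upper = edges[k + 1]
        if k == n_classes - 1:
            in_class = (v_geo >= edges[k]) & (v_geo <= upper)
        else:
            in_class = (v_geo >= edges[k]) & (v_geo < upper)
        row = {
            "class": k + 1,
            "lower_km": edges[k],
            "upper_km": upper,
            "midpoint_km": 0.5 * (edges[k] + upper),
            "n_pairs": int(in_class.sum()),
        }
        if in_class.sum() == 0 or in_class.all() or np.std(v_gen) == 0:
            row.update({"r": np.nan, "p": np.nan})
        else:
            indicator = np.zeros((n, n))
            indicator[iu] = in_class
            indicator += indicator.T
            res = _signed_class_mantel(v_gen, indicator, iu, n_perm, rng)
            row.update(res)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_corrected"] = _progressive_holm(out["p"].to_numpy())
    return out


def _signed_class_mantel(v_gen, indicator, iu, n_perm, rng) -> dict:
    """One-tailed Mantel test of within-class similarity.

    The raw correlation between genetic distance and the in-class indicator
    is negated, so r > 0 when within-class pairs are closer than average.
    """
    v_ind = indicator[iu]
    n = indicator.shape[0]
    r = -float(np.corrcoef(v_gen, v_ind)[0, 1])
    zg = (v_gen - v_gen.mean()) / v_gen.std()
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = indicator[np.ix_(perm, perm)][iu]
        rp = -float(np.mean(zg * (vp - vp.mean()) / vp.std()))
        if rp >= r - 1e-12:
            count += 1
    return {"r": r, "p": count / (n_perm + 1)}


def _progressive_holm(p: np.ndarray) -> np.ndarray:
    """Progressive multiple-testing correction for correlograms.

    Class k is corrected by Holm's method over the first k classes only,
    matching the usual progressive correction for correlograms.
    """
    out = np.full_like(p, np.nan, dtype=float)
    for k in range(len(p)):
        if np.isnan(p[k]):
            continue
        prefix = p[: k + 1]
        valid = prefix[~np.isnan(prefix)]
        order = np.argsort(valid)
        m = len(valid)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * valid[idx])
            adj[idx] = min(1.0, running)
        # index of p[k] within valid prefix
        k_valid = (~np.isnan(prefix)).sum() - 1
        out[k] = adj[k_valid]
    return out


def hellinger_abundance_distance(abundance: pd.DataFrame) -> DistanceMatrix:
    """Hellinger distance between site composition profiles.

    Rows are sites, columns genotype groups, entries nonnegative counts.
    Each row is converted to relative abundances, square-rooted, and compared
    by Euclidean distance; values are bounded by sqrt(2).
    """
    counts = abundance.to_numpy(dtype=float)
    if (counts < 0).any():
        raise KleptopopError("negative abundance")
    row_sums = counts.sum(axis=1)
    if (row_sums <= 0).any():
        bad = list(abundance.index[row_sums <= 0])
        raise KleptopopError(f"zero-abundance rows: {bad}")
    rel = np.sqrt(counts / row_sums[:, None])
    diff = rel[:, None, :] - rel[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(list(abundance.index), values)


def abundance_table(dataset) -> pd.DataFrame:
    """Site x group abundance counts of assigned individuals."""
    rows = {}
    for ind in dataset.individuals:
        if ind.group in ("UNASSIGNED",):
            continue
        rows.setdefault(ind.site, {}).setdefault(ind.group, 0)
        rows[ind.site][ind.group] += 1
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    df = df.sort_index()
    return df[sorted(df.columns)]
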