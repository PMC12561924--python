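"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (closed forms, full recomputation,
brute force) and shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def haversine_deg(lon1, lat1, lon2, lat2):
    """Great-circle central angle via the classic haversine formula."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2) - np.deg2rad(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return np.rad2deg(2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def quat_to_matrix(w, x, y, z):
    """Rotation matrix of a scalar-first unit quaternion, by the textbook formula."""
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _pairwise_dispersion_deg(vecs):
    """Max pairwise angle, recomputed from scratch over all pairs."""
    worst = 0.0
    for a in range(len(vecs)):
        for b in range(a + 1, len(vecs)):
            d = float(np.clip(np.dot(vecs[a], vecs[b]), -1.0, 1.0))
            worst = max(worst, np.degrees(np.arccos(d)))
    return worst


def brute_idt(t, vec, dispersion_deg=3.0, min_dur_ms=80.0):
    """Brute-force dispersion-threshold fixation detection.

    Same greedy scheduling contract as the package (grow while the maximal
    pairwise geodesic extent stays within threshold; emit windows spanning
    the minimum duration; restart after the emitted window, else slide by
    one) but with the dispersion recomputed over all pairs at every step.
    Returns (start, end) inclusive index pairs.
    """
    n = len(t)
    min_dur = min_dur_ms / 1000.0
    out = []
    i = 0
    while i < n:
        j = None
        for k in range(i, n):
            if t[k] - t[i] >= min_dur:
                j = k
                break
        if j is None:
            break
        if _pairwise_dispersion_deg(vec[i : j + 1]) > dispersion_deg:
            i += 1
            continue
        while j + 1 < n and _pairwise_dispersion_deg(vec[i : j + 2]) <= dispersion_deg:
            j += 1
        out.append((i, j))
        i = j + 1
    return out


def oneway_rm_anova(table):
    """Hand sums-of-squares decomposition of a one-way within design.

    ``table``: 2-D array, rows = subjects, columns = levels.  Returns
    (F, df1, df2, eta_g2) with generalized eta-squared for a fully
    manipulated design.
    """
    x = np.asarray(table, dtype=float)
    s, a = x.shape
    grand = x.mean()
    ss_a = s * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_s = a * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_t = np.sum((x - grand) ** 2)
    ss_err = ss_t - ss_a - ss_s
    df1, df2 = a - 1, (a - 1) * (s - 1)
    f = (ss_a / df1) / (ss_err / df2)
    eta_g2 = ss_a / (ss_a + ss_s + ss_err)
    return f, df1, df2, eta_g2


def mc_union_of_caps(centers_lonlat, theta_deg, n_points=1_000_000, seed=0):
    """Monte-Carlo union-of-caps area as (percent, standard error percent)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    cos_thr = np.cos(np.deg2rad(theta_deg))
    hit = np.zeros(n_points, dtype=bool)
    for lon, lat in centers_lonlat:
        lam, phi = np.deg2rad(lon), np.deg2rad(lat)
        c = np.array([np.cos(phi) * np.cos(lam), -np.cos(phi) * np.sin(lam), np.sin(phi)])
        hit |= pts @ c >= cos_thr
    p = hit.mean()
    return 100.0 * p, 100.0 * np.sqrt(p * (1 - p) / n_points)
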