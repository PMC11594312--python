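"""Independent brute-force oracles used to check the implementation.

Everything here is written as plain loops / exhaustive enumeration,
deliberately ignoring the vectorized or heuristic code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    a = (
        math.sin((p2 - p1) / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def greedy_thin(points, min_km):
    kept = []
    for lat, lon in points:
        ok = True
        for klat, klon in kept:
            if haversine(lat, lon, klat, klon) < min_km:
                ok = False
                break
        if ok:
            kept.append((lat, lon))
    return kept


def auc_all_pairs(presence, background):
    wins = 0.0
    for p in presence:
        for b in background:
            if p > b:
                wins += 1.0
            elif p == b:
                wins += 0.5
    return wins / (len(presence) * len(background))


def boyce_windows(presence, background, n_windows, width):
    """Explicit window-loop continuous Boyce index (Spearman via ranks)."""
    combined = list(presence) + list(background)
    lo, hi = min(combined), max(combined)
    mids, ratios = [], []
    for i in range(n_windows):
        start = lo + i * (hi - width - lo) / (n_windows - 1)
        end = start + width
        p = sum(1 for s in presence if start <= s <= end) / len(presence)
        e = sum(1 for s in background if start <= s <= end) / len(background)
        if e == 0:
            continue
        mids.append(start + width / 2)
        ratios.append(p / e)
    if len(ratios) < 3:
        return None

    def ranks(xs):
        order = sorted(range(len(xs)), key=lambda i: xs[i])
        r = [0.0] * len(xs)
        i = 0
        while i < len(xs):
            j = i
            while j + 1 < len(xs) and xs[order[j + 1]] == xs[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rm, rr = ranks(mids), ranks(ratios)
    mm, mr = sum(rm) / len(rm), sum(rr) / len(rr)
    num = sum((a - mm) * (b - mr) for a, b in zip(rm, rr))
    den = math.sqrt(sum((a - mm) ** 2 for a in rm) * sum((b - mr) ** 2 for b in rr))
    return None if den == 0 else num / den


def richness_loops(layer_arrays):
    """Per-cell presence count over a list of 2-D arrays (NaN = missing)."""
    n_rows, n_cols = layer_arrays[0].shape
    out = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            total, any_valid = 0, False
            for arr in layer_arrays:
                v = arr[r, c]
                if not np.isnan(v):
                    any_valid = True
                    total += int(v)
            out[r, c] = total if any_valid else np.nan
    return out


def nodf_loops(mat):
    mat = np.asarray(mat)
    P, A = mat.shape
    terms = []
    for axis_mat, n in ((mat, P), (mat.T, A)):
        fills = [int(axis_mat[i].sum()) for i in range(n)]
        for u in range(n):
            for v in range(u + 1, n):
                hi, lo = (u, v) if fills[u] >= fills[v] else (v, u)
                if fills[hi] > fills[lo] > 0:
                    shared = sum(
                        1 for k in range(axis_mat.shape[1]) if axis_mat[hi, k] and axis_mat[lo, k]
                    )
                    terms.append(100.0 * shared / fills[lo])
                else:
                    terms.append(0.0)
    return sum(terms) / len(terms)


def metaweb_and_loops(links, allowed):
    out = np.zeros_like(links)
    for i in range(links.shape[0]):
        for j in range(links.shape[1]):
            out[i, j] = 1 if (links[i, j] == 1 and allowed[i, j] == 1) else 0
    return out


def entropy_linkage_density(mat):
    """Bersier-style quantitative linkage density via explicit 2^H."""
    mat = np.asarray(mat, dtype=float)
    m = mat.sum()
    total = 0.0
    for axis_mat in (mat, mat.T):
        for i in range(axis_mat.shape[0]):
            row = axis_mat[i]
            b = row.sum()
            if b == 0:
                continue
            H = 0.0
            for w in row:
                if w > 0:
                    p = w / b
                    H -= p * math.log2(p)
            total += (b / m) * 2**H
    return total / 2.0


def set_partitions(items):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    n = len(items)

    def rec(idx, groups):
        if idx == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[idx])
            yield from rec(idx + 1, groups)
            g.pop()
        groups.append([items[idx]])
        yield from rec(idx + 1, groups)
        groups.pop()

    yield from rec(0, [])


def barber_q_loops(mat, row_labels, col_labels):
    mat = np.asarray(mat, dtype=float)
    L = mat.sum()
    q = 0.0
    k = mat.sum(axis=1)
    d = mat.sum(axis=0)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if row_labels[i] == col_labels[j]:
                q += mat[i, j] - k[i] * d[j] / L
    return q / L


def max_modularity_enumeration(mat):
    """Exact maximum Barber Q over all partitions of the P + A nodes."""
    mat = np.asarray(mat)
    P, A = mat.shape
    nodes = list(range(P + A))
    best = -np.inf
    for partition in set_partitions(nodes):
        row_labels = [0] * P
        col_labels = [0] * A
        for g, group in enumerate(partition):
            for node in group:
                if node < P:
                    row_labels[node] = g
                else:
                    col_labels[node - P] = g
        best = max(best, barber_q_loops(mat, row_labels, col_labels))
    return best


def extinction_area(mat, removal_cols):
    """Trapezoidal area for one removal order (columns removed)."""
    mat = np.asarray(mat).astype(bool).copy()
    n_rows, S = mat.shape
    ys = [1.0]
    for col in removal_cols:
        mat[:, col] = False
        survivors = sum(1 for r in range(n_rows) if mat[r].any())
        ys.append(survivors / n_rows)
    area = 0.0
    for k in range(1, S + 1):
        area += (1.0 / S) * (ys[k - 1] + ys[k]) / 2.0
    return area


def robustness_exact(mat):
    """Mean and SD of the extinction area over all S! removal orders."""
    S = np.asarray(mat).shape[1]
    areas = [extinction_area(mat, perm) for perm in itertools.permutations(range(S))]
    return float(np.mean(areas)), float(np.std(areas))
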