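"""Brute-force reference implementations for validation.

These deliberately trade speed for transparency: exhaustive enumeration and
plain per-element loops, written against the method definitions rather than
sharing code with the production implementations, so that agreement between
the two routes is meaningful evidence of correctness. Suitable only for
small problems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import C13_C12_SPACING
from .deisotope import IsotopeGroup

__all__ = [
    "brute_force_isotope_groups",
    "brute_force_upgma",
    "merges_from_linkage",
    "direct_combat",
]


# ---------------------------------------------------------------------------
# De-isotoping oracle
# ---------------------------------------------------------------------------

def _pair_valid(i, j, mz, rt, vals, mean_int, ppm_tol, rt_tol, r_min, ratio_min):
    expected = mz[i] + C13_C12_SPACING
    if abs(mz[j] - expected) / expected * 1e6 > ppm_tol:
        return False
    if abs(rt[j] - rt[i]) > rt_tol:
        return False
    ok = ~(np.isnan(vals[i]) | np.isnan(vals[j]))
    if ok.sum() < 3:
        return False
    x, y = vals[i][ok], vals[j][ok]
    if x.std() == 0 or y.std() == 0:
        return False
    if np.corrcoef(x, y)[0, 1] <= r_min:
        return False
    if not (mean_int[j] > 0) or mean_int[i] / mean_int[j] <= ratio_min:
        return False
    return True


def brute_force_isotope_groups(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    ppm_tol: float = 20.0,
    rt_tol: float = 0.2,
    r_min: float = 0.9,
    ratio_min: float = 2.0,
) -> list[IsotopeGroup]:
    """Exhaustively test every ordered peak pair (and triple extension)
    against the four isotope-group criteria, then assemble disjoint groups
    greedily in descending monoisotopic mean intensity with ties broken by
    ascending m/z, preferring the partner nearest the expected spacing."""
    ann = annot.set_index("peak_id").loc[matrix.index]
    mz = ann["mz"].to_numpy(dtype=float)
    rt = ann["rt"].to_numpy(dtype=float)
    vals = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_int = np.nanmean(vals, axis=1)
    ids = list(matrix.index)
    n = len(ids)

    valid = {}
    for i in range(n):
        for j in range(n):
            if i != j and _pair_valid(i, j, mz, rt, vals, mean_int,
                                      ppm_tol, rt_tol, r_min, ratio_min):
                valid[(i, j)] = True

    def partner_order(i, cands):
        expected = mz[i] + C13_C12_SPACING
        return sorted(cands, key=lambda j: (abs(mz[j] - expected), mz[j]))

    taken = [False] * n
    groups = []
    for i in sorted(range(n), key=lambda i: (-mean_int[i], mz[i])):
        if taken[i]:
            continue
        partners = partner_order(i, [j for (a, j) in valid if a == i
                                     and not taken[j]])
        if not partners:
            continue
        j = partners[0]
        extensions = partner_order(j, [k for (a, k) in valid
                                       if a == j and not taken[k] and k != i])
        k = extensions[0] if extensions else None

        def corr(a, b):
            ok = ~(np.isnan(vals[a]) | np.isnan(vals[b]))
            return float(np.corrcoef(vals[a][ok], vals[b][ok])[0, 1])

        if k is None:
            g = IsotopeGroup(ids[i], ids[j], None, corr(i, j),
                             float(mean_int[i] / mean_int[j]), None)
        else:
            g = IsotopeGroup(ids[i], ids[j], ids[k],
                             min(corr(i, j), corr(j, k)),
                             float(mean_int[i] / mean_int[j]),
                             float(mean_int[j] / mean_int[k]))
        groups.append(g)
        for pid in g.members:
            taken[ids.index(pid)] = True
    return groups


# ---------------------------------------------------------------------------
# UPGMA oracle
# ---------------------------------------------------------------------------

def brute_force_upgma(dist: np.ndarray) -> list[tuple[float, frozenset]]:
    """Step-by-step UPGMA on a square distance matrix.

    Returns the merge list as (height, leaves-in-new-cluster) tuples, where
    height is half the average linkage distance at the merge.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {frozenset([i, j]): float(dist[i, j])
         for i in range(n) for j in range(i + 1, n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                dd = d[frozenset([a, b])]
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best
        new = max(clusters) + 1
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] | clusters[b]
        for c in keys:
            if c in (a, b):
                continue
            d[frozenset([new, c])] = (
                na * d[frozenset([a, c])] + nb * d[frozenset([b, c])]
            ) / (na + nb)
        del clusters[a], clusters[b]
        clusters[new] = merged
        merges.append((dd / 2.0, merged))
    return merges


def merges_from_linkage(Z: np.ndarray, n: int) -> list[tuple[float, frozenset]]:
    """Convert a scipy linkage matrix into the oracle's merge-list form."""
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + step] = merged
        merges.append((float(h) / 2.0, merged))
    return merges


# ---------------------------------------------------------------------------
# Direct (non-vectorized) EB batch correction
# ---------------------------------------------------------------------------

def direct_combat(data: np.ndarray, batch: np.ndarray, conv: float = 1e-4) -> np.ndarray:
    """Plain-loop parametric EB location/scale batch adjustment, one peak
    and one batch at a time, following the model definition directly."""
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    levels = sorted(set(batch.tolist()))
    n_peaks, n_samples = data.shape
    idx_of = {lev: [s for s in range(n_samples) if batch[s] == lev]
              for lev in levels}

    # per-peak standardization
    alpha = np.zeros(n_peaks)
    sigma = np.zeros(n_peaks)
    z = np.zeros_like(data)
    for g in range(n_peaks):
        total_n = 0
        a = 0.0
        for lev in levels:
            obs = [data[g, s] for s in idx_of[lev] if not np.isnan(data[g, s])]
            a += len(obs) * (sum(obs) / len(obs))
            total_n += len(obs)
        alpha[g] = a / total_n
        sse = 0.0
        for lev in levels:
            obs = [data[g, s] for s in idx_of[lev] if not np.isnan(data[g, s])]
            mu = sum(obs) / len(obs)
            sse += sum((o - mu) ** 2 for o in obs)
        sigma[g] = max(np.sqrt(sse / total_n), 1e-6)
        for s in range(n_samples):
            z[g, s] = (data[g, s] - alpha[g]) / sigma[g]

    out = np.array(z)
    for lev in levels:
        cols = idx_of[lev]
        g_hat = np.array([np.nanmean(z[g, cols]) for g in range(n_peaks)])
        d_hat = np.array([np.nanvar(z[g, cols], ddof=1) for g in range(n_peaks)])
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        m = float(np.mean(d_hat))
        v = float(np.var(d_hat, ddof=1))
        a_prior = (2 * v + m ** 2) / v
        b_prior = (m * v + m ** 3) / v

        n_g = np.array([sum(1 for s in cols if not np.isnan(z[g, s]))
                        for g in range(n_peaks)], dtype=float)
        g_old, d_old = g_hat.copy(), d_hat.copy()
        while True:
            g_new = np.empty(n_peaks)
            d_new = np.empty(n_peaks)
            for g in range(n_peaks):
                g_new[g] = (t2 * n_g[g] * g_hat[g] + d_old[g] * g_bar) / \
                           (t2 * n_g[g] + d_old[g])
                sum2 = float(np.nansum((z[g, cols] - g_new[g]) ** 2))
                d_new[g] = (0.5 * sum2 + b_prior) / (n_g[g] / 2.0 + a_prior - 1.0)
            change = max(
                max(abs(g_new[g] - g_old[g]) / abs(g_old[g]) for g in range(n_peaks)),
                max(abs(d_new[g] - d_old[g]) / abs(d_old[g]) for g in range(n_peaks)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        for g in range(n_peaks):
            for s in cols:
                out[g, s] = (z[g, s] - g_old[g]) / np.sqrt(d_old[g])

    for g in range(n_peaks):
        for s in range(n_samples):
            out[g, s] = out[g, s] * sigma[g] + alpha[g]
    return out
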