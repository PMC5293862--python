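"""In-house de-isotoping of [M]/[M+1]/[M+2] peak groups.

A candidate isotope partner sits one 13C-12C spacing (1.00336 Da, charge 1)
above its parent within a +/-20 ppm window and elutes at approximately the
same apex retention time (+/-0.2 min). The group's intensities must be
highly correlated across samples (Pearson r > 0.9), and the mean-intensity
ratios must satisfy [M]/[M+1] > 2 and [M+1]/[M+2] > 2 — the envelope of a
singly charged small molecule with < ~46 carbons. Only the monoisotopic
ion of an accepted group is retained downstream.

Groups are assembled greedily in descending monoisotopic mean intensity
(ties broken by ascending m/z) and are disjoint: a peak joins at most one
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import C13_C12_SPACING

__all__ = ["IsotopeGroup", "find_isotope_groups", "deisotope", "groups_to_frame"]


@dataclass(frozen=True)
class IsotopeGroup:
    monoisotopic: str
    plus_one: str
    plus_two: str | None
    correlation: float           # min pairwise r along the chain
    ratio_m_m1: float
    ratio_m1_m2: float | None

    @property
    def members(self) -> list[str]:
        out = [self.monoisotopic, self.plus_one]
        if self.plus_two is not None:
            out.append(self.plus_two)
        return out


def _pearson(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> float | None:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_n:
        return None
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def _partner_ok(
    mz_lo: float, rt_lo: float, mz_hi: float, rt_hi: float,
    ppm_tol: float, rt_tol: float,
) -> bool:
    expected = mz_lo + C13_C12_SPACING
    return (abs(mz_hi - expected) / expected * 1e6 <= ppm_tol
            and abs(rt_hi - rt_lo) <= rt_tol)


def find_isotope_groups(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    ppm_tol: float = 20.0,
    rt_tol: float = 0.2,
    r_min: float = 0.9,
    ratio_min: float = 2.0,
) -> list[IsotopeGroup]:
    """Find disjoint [M]/[M+1](/[M+2]) groups satisfying all four criteria
    (mass spacing + RT window, correlation, both intensity ratios)."""
    ann = annot.set_index("peak_id").loc[matrix.index]
    mz = ann["mz"].to_numpy(dtype=float)
    rt = ann["rt"].to_numpy(dtype=float)
    vals = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_int = np.nanmean(vals, axis=1)
    ids = list(matrix.index)
    n = len(ids)

    # seeds in descending mean intensity, ties by ascending m/z
    seed_order = sorted(range(n), key=lambda i: (-mean_int[i], mz[i]))
    taken = np.zeros(n, dtype=bool)
    groups: list[IsotopeGroup] = []

    mz_sort = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_sort]

    def candidates(i: int) -> list[int]:
        """Partner candidates one spacing above peak i, same RT window,
        sorted for deterministic preference: nearest expected m/z first."""
        expected = mz[i] + C13_C12_SPACING
        tol = expected * ppm_tol * 1e-6
        lo = np.searchsorted(mz_sorted, expected - tol, side="left")
        hi = np.searchsorted(mz_sorted, expected + tol, side="right")
        cand = [int(mz_sort[k]) for k in range(lo, hi)]
        cand = [j for j in cand if not taken[j] and j != i
                and abs(rt[j] - rt[i]) <= rt_tol]
        return sorted(cand, key=lambda j: (abs(mz[j] - expected), mz[j]))

    for i in seed_order:
        if taken[i]:
            continue
        best = None
        for j in candidates(i):
            r1 = _pearson(vals[i], vals[j])
            if r1 is None or r1 <= r_min:
                continue
            if not (mean_int[j] > 0) or mean_int[i] / mean_int[j] <= ratio_min:
                continue
            # optionally extend to [M+2]
            m2_choice = None
            for k in candidates(j):
                if k == i:
                    continue
                r2 = _pearson(vals[j], vals[k])
                if r2 is None or r2 <= r_min:
                    continue
                if not (mean_int[k] > 0) or mean_int[j] / mean_int[k] <= ratio_min:
                    continue
                m2_choice = (k, r2)
                break
            if m2_choice is None:
                best = IsotopeGroup(ids[i], ids[j], None, r1,
                                    float(mean_int[i] / mean_int[j]), None)
            else:
                k, r2 = m2_choice
                best = IsotopeGroup(ids[i], ids[j], ids[k], min(r1, r2),
                                    float(mean_int[i] / mean_int[j]),
                                    float(mean_int[j] / mean_int[k]))
            break
        if best is not None:
            groups.append(best)
            for pid in best.members:
                taken[ids.index(pid)] = True
    return groups


def deisotope(matrix: pd.DataFrame, groups: list[IsotopeGroup]) -> pd.DataFrame:
    """Drop [M+1]/[M+2] rows; monoisotopic rows are untouched."""
    drop = set()
    for g in groups:
        drop.add(g.plus_one)
        if g.plus_two is not None:
            drop.add(g.plus_two)
    return matrix.loc[[pid for pid in matrix.index if pid not in drop]]


def groups_to_frame(groups: list[IsotopeGroup]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "monoisotopic_id": g.monoisotopic,
            "partner_ids": ";".join(g.members[1:]),
            "r": g.correlation,
            "ratio_m_m1": g.ratio_m_m1,
            "ratio_m1_m2": g.ratio_m1_m2,
        }
        for g in groups
    ], columns=["monoisotopic_id", "partner_ids", "r", "ratio_m_m1", "ratio_m1_m2"])
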