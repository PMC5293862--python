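"""Rule-based annotation of flavonoid glycosides and alkaloids.

Three lines of evidence are collected for a peak: (1) its 13C isotope
partner must be present in the peak annotation table with a retention time
inside the peak's [rtmin, rtmax]; (2) highly correlated co-eluting peaks
are grouped and treated as in-source fragments; (3) the parent/fragment
masses are decomposed into an aglycone plus an ordered chain of neutral
losses (hexose 162.0528, deoxyhexose 146.0579, acetylhexose 204.0634,
malonylhexose 248.0532, feruloylhexose 338.1002 Da).

Annotation names the aglycone type and the type and number of sugar/acyl
moieties, never glycosylation positions or linkages; moiety symbols are
joined aglycone-outward, e.g. ``K-Glc-maGlc``. Kaempferol and luteolin
share a formula, so a kaempferol match is always reported with the isomer
ambiguity flagged rather than resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    AGLYCONE_LIBRARY,
    MOIETY_LIBRARY,
    C13_C12_SPACING,
    Aglycone,
    Moiety,
    ppm_error,
)

__all__ = [
    "Evidence",
    "AnnotationResult",
    "check_isotopic_presence",
    "coeluting_group",
    "annotate_glycoside",
    "annotate_peaks",
]


@dataclass(frozen=True)
class Evidence:
    criterion: str
    passed: bool
    detail: str


@dataclass
class AnnotationResult:
    peak_id: str | None
    aglycone: str | None                 # aglycone name, or None
    ambiguous_aglycones: list[str] = field(default_factory=list)
    moieties: list[str] = field(default_factory=list)  # names, aglycone-outward
    residual_ppm: float | None = None
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return self.aglycone is not None

    @property
    def rendered_name(self) -> str | None:
        if not self.annotated:
            return None
        parts = [AGLYCONE_LIBRARY[self.aglycone].symbol]
        parts += [MOIETY_LIBRARY[m].symbol for m in self.moieties]
        return "-".join(parts)


# ---------------------------------------------------------------------------
# Evidence criteria
# ---------------------------------------------------------------------------

def check_isotopic_presence(
    peak_id: str,
    annot: pd.DataFrame,
    ppm_tol: float = 20.0,
) -> Evidence:
    """Pass iff a peak one 13C spacing above exists whose apex RT lies
    within the target's [rtmin, rtmax]."""
    ann = annot.set_index("peak_id")
    row = ann.loc[peak_id]
    expected = row["mz"] + C13_C12_SPACING
    tol = expected * ppm_tol * 1e-6
    cands = ann[(ann["mz"] >= expected - tol) & (ann["mz"] <= expected + tol)]
    cands = cands[(cands["rt"] >= row["rtmin"]) & (cands["rt"] <= row["rtmax"])]
    if len(cands):
        return Evidence("isotopic_presence", True,
                        f"partner {cands.index[0]} at {cands['mz'].iloc[0]:.4f}")
    return Evidence("isotopic_presence", False,
                    f"no peak near {expected:.4f} within [rtmin, rtmax]")


def coeluting_group(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    seed_peak: str,
    r_min: float = 0.9,
    rt_tol: float = 0.05,
) -> list[str]:
    """Peaks co-eluting with the seed (apex RT within ``rt_tol``) whose
    intensities correlate with it (Pearson r > ``r_min`` over >= 3 shared
    samples), sorted by descending m/z. Includes the seed."""
    if seed_peak not in matrix.index:
        raise KeyError(f"seed peak {seed_peak!r} not in matrix")
    ann = annot.set_index("peak_id").loc[matrix.index]
    seed_rt = ann.at[seed_peak, "rt"]
    x = matrix.loc[seed_peak].to_numpy(dtype=float)
    out = []
    for pid in matrix.index:
        if abs(ann.at[pid, "rt"] - seed_rt) > rt_tol:
            continue
        if pid == seed_peak:
            out.append(pid)
            continue
        y = matrix.loc[pid].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue  # too few shared samples; skip with no claim
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        if np.corrcoef(x[ok], y[ok])[0, 1] > r_min:
            out.append(pid)
    return sorted(out, key=lambda pid: -ann.at[pid, "mz"])


# ---------------------------------------------------------------------------
# Neutral-loss decomposition
# ---------------------------------------------------------------------------

def _aglycone_candidates(adduct: str) -> list[tuple[Aglycone, float]]:
    out = []
    for a in AGLYCONE_LIBRARY.values():
        try:
            out.append((a, a.ion_mz(adduct)))
        except ValueError:
            continue
    return out


def _isomeric_partners(agly: Aglycone) -> list[str]:
    if agly.formula is None:
        return []
    return [a.name for a in AGLYCONE_LIBRARY.values()
            if a.name != agly.name and a.formula == agly.formula]


def _chain_from_fragments(
    parent_mz: float,
    fragments: list[float],
    aglycone_mz: float,
    moieties: list[Moiety],
    ppm_tol: float,
) -> list[str] | None:
    """Walk parent -> fragments -> aglycone, explaining each step as one
    moiety loss evidenced by an observed mass difference. Returns moiety
    names in loss order, or None if no full chain exists."""
    ladder = sorted({f for f in fragments
                     if aglycone_mz - 1e-3 <= f <= parent_mz - 1.0},
                    reverse=True)
    ladder = [parent_mz] + ladder + [aglycone_mz]

    def step(cur: float, remaining: list[float]) -> list[str] | None:
        if ppm_error(cur, aglycone_mz) <= ppm_tol:
            return []
        for nxt in remaining:
            if nxt >= cur - 1.0:
                continue
            delta = cur - nxt
            for m in moieties:
                if abs(delta - m.loss_mass) <= cur * ppm_tol * 1e-6 + 1e-9:
                    rest = step(nxt, [f for f in remaining if f < nxt + 1e-9])
                    if rest is not None:
                        return [m.name] + rest
        return None

    return step(ladder[0], ladder[1:])


def _brute_force_losses(
    gap: float,
    moieties: list[Moiety],
    parent_mz: float,
    ppm_tol: float,
    max_moieties: int = 3,
) -> list[list[str]]:
    """All moiety multisets (up to ``max_moieties``) whose summed losses
    explain ``gap`` within the ppm window, fewest moieties first then
    lexicographic by symbol."""
    tol = parent_mz * ppm_tol * 1e-6
    hits = []
    for k in range(0, max_moieties + 1):
        for combo in itertools.combinations_with_replacement(
                sorted(moieties, key=lambda m: m.symbol), k):
            if abs(sum(m.loss_mass for m in combo) - gap) <= tol:
                hits.append([m.name for m in combo])
    return hits


def annotate_glycoside(
    parent_mz: float,
    fragment_mzs: list[float],
    aglycones: dict[str, Aglycone] | None = None,
    moieties: dict[str, Moiety] | None = None,
    adduct: str = "[M+H]+",
    ppm_tol: float = 20.0,
    peak_id: str | None = None,
) -> AnnotationResult:
    """Greedy aglycone + neutral-loss decomposition of a parent ion and its
    co-eluting in-source fragments.

    Preference order: losses directly evidenced by observed fragment mass
    differences, then fewest moieties, then lexicographic symbol order.
    The returned moiety list is ordered aglycone-outward (reverse of the
    loss order from the parent), matching names like ``K-Glc-maGlc``.
    Absence of an annotation is a result, not an error.
    """
    if parent_mz <= 0:
        raise ValueError("parent_mz must be positive")
    aglycones = aglycones or AGLYCONE_LIBRARY
    moieties = moieties or MOIETY_LIBRARY
    moi_list = list(moieties.values())
    result = AnnotationResult(peak_id=peak_id, aglycone=None)

    # candidate aglycones matched against any observed ion (or implied by
    # the parent minus a valid loss chain), nearest mass first
    observed = [parent_mz] + list(fragment_mzs)
    cands: list[tuple[float, Aglycone, float, bool]] = []
    for agly in aglycones.values():
        try:
            ion = agly.ion_mz(adduct)
        except ValueError:
            continue
        direct = [o for o in observed if ppm_error(o, ion) <= ppm_tol]
        if direct:
            err = min(ppm_error(o, ion) for o in direct)
            cands.append((err, agly, ion, True))
        elif ion <= parent_mz + 1e-6:
            cands.append((ppm_tol, agly, ion, False))
    cands.sort(key=lambda t: (not t[3], t[0], t[1].symbol))

    for err, agly, ion, direct in cands:
        gap = parent_mz - ion
        if gap < -parent_mz * ppm_tol * 1e-6:
            continue
        if abs(gap) <= parent_mz * ppm_tol * 1e-6:
            losses: list[str] | None = []
        else:
            losses = _chain_from_fragments(parent_mz, list(fragment_mzs),
                                           ion, moi_list, ppm_tol)
            evidenced = losses is not None
            if losses is None:
                hits = _brute_force_losses(gap, moi_list, parent_mz, ppm_tol)
                losses = hits[0] if hits else None
            if losses is None:
                continue
            if not evidenced and not direct:
                # neither the aglycone ion nor any loss step was observed
                continue
        result.aglycone = agly.name
        result.ambiguous_aglycones = _isomeric_partners(agly)
        result.moieties = list(reversed(losses))  # aglycone-outward
        recomposed = ion + sum(moieties[m].loss_mass for m in losses)
        result.residual_ppm = ppm_error(parent_mz, recomposed)
        result.evidence.append(Evidence(
            "fragment_match", True,
            f"aglycone {agly.symbol} at {ion:.4f} "
            f"({'observed' if direct else 'inferred'}), "
            f"losses {losses}, residual {result.residual_ppm:.2f} ppm"))
        if result.ambiguous_aglycones:
            result.evidence.append(Evidence(
                "aglycone_ambiguity", True,
                f"{agly.symbol} indistinguishable from "
                f"{'/'.join(result.ambiguous_aglycones)} by mass"))
        if any(m in ("hexose", "deoxyhexose") for m in result.moieties):
            result.evidence.append(Evidence(
                "sugar_assumption", True,
                "hexose reported as Glc, deoxyhexose as Rha by convention"))
        return result

    result.evidence.append(Evidence(
        "fragment_match", False,
        "no aglycone + moiety decomposition within tolerance"))
    return result


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def annotate_peaks(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    peak_ids: list[str] | None = None,
    adduct: str = "[M+H]+",
    ppm_tol: float = 20.0,
    r_min: float = 0.9,
    rt_tol: float = 0.05,
) -> pd.DataFrame:
    """Annotate peaks using isotope presence + co-elution + neutral losses.

    For each target peak the co-eluting correlated group supplies the
    candidate fragment ions (all members below the target m/z).
    """
    targets = list(peak_ids) if peak_ids is not None else list(matrix.index)
    ann = annot.set_index("peak_id")
    rows = []
    for pid in targets:
        iso = check_isotopic_presence(pid, annot, ppm_tol)
        group = coeluting_group(matrix, annot, pid, r_min=r_min, rt_tol=rt_tol)
        parent_mz = float(ann.at[pid, "mz"])
        frags = [float(ann.at[q, "mz"]) for q in group
                 if q != pid and ann.at[q, "mz"] < parent_mz - 1.0]
        res = annotate_glycoside(parent_mz, frags, adduct=adduct,
                                 ppm_tol=ppm_tol, peak_id=pid)
        res.evidence.insert(0, iso)
        res.evidence.insert(1, Evidence(
            "coelution_group", len(group) > 1,
            f"{len(group)} correlated co-eluting peaks"))
        rows.append({
            "peak_id": pid,
            "name": res.rendered_name,
            "aglycone": res.aglycone,
            "ambiguous_aglycones": "/".join(res.ambiguous_aglycones),
            "moieties": ";".join(res.moieties),
            "residual_ppm": res.residual_ppm,
            "isotopic_presence": iso.passed,
            "n_coeluting": len(group),
            "evidence": " | ".join(
                f"{e.criterion}:{'pass' if e.passed else 'fail'}"
                for e in res.evidence),
        })
    return pd.DataFrame(rows)
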