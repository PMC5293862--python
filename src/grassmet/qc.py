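"""Quality-control filtering of multi-batch peak tables.

Fixed stage order: duplicate-peak merging -> empirical-Bayes batch
correction -> residual-batch F-filter -> replicate-outlier removal
(modified Z-score within high-cv clonal groups) -> population-invariance
filter. No filter alters a surviving intensity except batch correction;
the others only drop rows or blank cells.

All model-based statistics (batch correction, ANOVA, PCA) operate on
natural-log intensities with a +1 offset; matrices are stored and returned
on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .combat import combat

__all__ = [
    "merge_duplicate_peaks",
    "correct_batch_effects",
    "filter_residual_batch",
    "replicate_cv",
    "CvReport",
    "modified_zscore",
    "remove_replicate_outliers",
    "filter_invariant_peaks",
    "pca_qc",
    "run_qc",
    "QcLog",
]


def _log(x: pd.DataFrame) -> np.ndarray:
    return np.log(x.to_numpy(dtype=float) + 1.0)


def _experimental(meta: pd.DataFrame) -> pd.DataFrame:
    return meta[~meta["is_control"].astype(bool)]


# ---------------------------------------------------------------------------
# Peak merging
# ---------------------------------------------------------------------------

def merge_duplicate_peaks(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    ppm_tol: float = 20.0,
    rt_tol: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Merge split detections of the same chromatographic peak.

    Peaks within ``ppm_tol`` m/z and ``rt_tol`` minutes (transitively) are
    merged into one row keeping the per-sample maximum; the merged row
    inherits the identity of its most intense member. Runs to a fixpoint so
    the operation is idempotent. Returns (matrix, annot, merge_log).
    """
    log: list[dict] = []
    while True:
        if matrix.empty:
            return matrix, annot, log
        ann = annot.set_index("peak_id").loc[matrix.index]
        mz = ann["mz"].to_numpy()
        rt = ann["rt"].to_numpy()
        order = np.argsort(mz, kind="stable")

        parent = np.arange(len(mz))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        # neighbours in m/z order are the only merge candidates
        for a in range(len(order)):
            ia = order[a]
            for b in range(a + 1, len(order)):
                ib = order[b]
                if (mz[ib] - mz[ia]) / mz[ib] * 1e6 > ppm_tol:
                    break
                if abs(rt[ib] - rt[ia]) <= rt_tol:
                    union(ia, ib)

        roots = np.array([find(i) for i in range(len(mz))])
        if len(np.unique(roots)) == len(mz):
            return matrix, annot, log

        vals = matrix.to_numpy(dtype=float)
        keep_rows, keep_ids = [], []
        new_annot_rows = []
        for root in pd.unique(roots):
            members = np.flatnonzero(roots == root)
            if len(members) == 1:
                i = members[0]
                keep_rows.append(vals[i])
                keep_ids.append(matrix.index[i])
                new_annot_rows.append(ann.iloc[i])
                continue
            sub = vals[members]
            merged = np.nanmax(sub, axis=0)
            mean_int = np.nanmean(sub, axis=1)
            lead = members[int(np.argmax(mean_int))]
            keep_rows.append(merged)
            keep_ids.append(matrix.index[lead])
            arow = ann.iloc[lead].copy()
            arow["rtmin"] = float(ann.iloc[members]["rtmin"].min())
            arow["rtmax"] = float(ann.iloc[members]["rtmax"].max())
            arow["mzmin"] = float(ann.iloc[members]["mzmin"].min())
            arow["mzmax"] = float(ann.iloc[members]["mzmax"].max())
            new_annot_rows.append(arow)
            log.append({
                "kept": matrix.index[lead],
                "merged": [matrix.index[i] for i in members if i != lead],
            })
        matrix = pd.DataFrame(np.vstack(keep_rows), index=keep_ids,
                              columns=matrix.columns)
        matrix.index.name = "peak_id"
        annot = pd.DataFrame(new_annot_rows)
        annot.index = keep_ids
        annot = annot.rename_axis("peak_id").reset_index()


# ---------------------------------------------------------------------------
# Batch correction + residual filter
# ---------------------------------------------------------------------------

def correct_batch_effects(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    Log-transforms internally, adjusts with batch as the (only) covariate,
    and returns intensities on the original scale (clipped at 0).
    """
    meta = meta.set_index("sample_id").loc[matrix.columns]
    corrected_log = combat(_log(matrix), meta["batch"].to_numpy())
    out = np.exp(corrected_log) - 1.0
    return pd.DataFrame(np.clip(out, 0.0, None), index=matrix.index,
                        columns=matrix.columns)


def _anova_p_by_group(log_vals: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-way ANOVA p per row; constant rows (F undefined) get p = 1."""
    levels = pd.unique(groups)
    ps = np.ones(log_vals.shape[0])
    masks = [groups == g for g in levels]
    for i in range(log_vals.shape[0]):
        samples = [log_vals[i, m] for m in masks]
        samples = [s[~np.isnan(s)] for s in samples]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            continue
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = sps.f_oneway(*samples)
        ps[i] = 1.0 if np.isnan(p) else p
    return ps


def filter_residual_batch(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop peaks whose log intensity still shows a batch effect
    (one-way ANOVA on batch, p < ``alpha``). Returns (filtered, p-values)."""
    meta = meta.set_index("sample_id").loc[matrix.columns]
    ps = _anova_p_by_group(_log(matrix), meta["batch"].to_numpy())
    pser = pd.Series(ps, index=matrix.index, name="batch_p")
    return matrix.loc[ps >= alpha], pser


# ---------------------------------------------------------------------------
# Replicate cv + outlier removal
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Replicate coefficient of variation per (peak, genotype), the
    per-peak median across genotypes, and the fraction of peaks whose
    median cv falls below the threshold."""

    per_genotype: pd.DataFrame     # peaks x genotypes
    median_cv: pd.Series           # per peak
    threshold: float
    fraction_below: float


def replicate_cv(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    cv_threshold: float = 0.3,
) -> CvReport:
    """cv = sd/mean over clonal replicates, per peak and genotype; missing
    values excluded; genotype cells with < 2 non-missing replicates are
    undefined and excluded from the per-peak median."""
    meta = meta.set_index("sample_id").loc[matrix.columns]
    exp_cols = matrix.columns[~meta["is_control"].to_numpy(dtype=bool)]
    genos = meta.loc[exp_cols, "genotype"]
    vals = matrix[exp_cols]

    cvs = {}
    for g, cols in exp_cols.groupby(genos).items():
        sub = vals[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
            cv = sd / mean
        cv[n < 2] = np.nan
        cvs[g] = cv
    per_geno = pd.DataFrame(cvs, index=matrix.index)
    median_cv = per_geno.median(axis=1, skipna=True)
    frac = float(np.mean(median_cv.dropna() < cv_threshold)) if len(median_cv.dropna()) else float("nan")
    return CvReport(per_geno, median_cv, cv_threshold, frac)


def modified_zscore(values: np.ndarray) -> np.ndarray:
    """Z_i = 0.6745 * (x_i - median(x)) / mad(x), mad unscaled.

    mad = 0 (constant input) yields all-zero scores: constant replicates
    have no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("modified_zscore: empty input")
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0 or np.isnan(mad):
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def remove_replicate_outliers(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    cv_trigger: float = 0.2,
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Blank outlier cells within high-variability clonal replicate groups.

    Only groups with cv > ``cv_trigger`` are examined; within them cells
    with |modified Z| > ``z_threshold`` are set missing, at most floor(n/2)
    per group. Removal iterates to a fixpoint (most extreme cell first,
    recomputing cv and Z after each removal), so a second pass over the
    output removes nothing. Returns (matrix, flagged cells).
    """
    meta_idx = meta.set_index("sample_id").loc[matrix.columns]
    exp_cols = matrix.columns[~meta_idx["is_control"].to_numpy(dtype=bool)]
    genos = meta_idx.loc[exp_cols, "genotype"]

    out = matrix.copy()
    flagged: list[tuple[str, str]] = []
    vals = out.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(out.columns)}
    for g, cols in exp_cols.groupby(genos).items():
        pos = [col_pos[c] for c in cols]
        sub = vals[:, pos]
        for ri in range(sub.shape[0]):
            # the cap counts all blanked cells in the group, so a group
            # capped once stays capped on any re-run
            cap = len(pos) // 2
            removed = int(np.sum(np.isnan(sub[ri])))
            while removed < cap:
                row = sub[ri]
                live = ~np.isnan(row)
                if live.sum() < 2:
                    break
                with np.errstate(invalid="ignore"):
                    cv = np.nanstd(row, ddof=1) / np.nanmean(row)
                if not (cv > cv_trigger):
                    break
                z = modified_zscore(row)
                z = np.where(live, z, 0.0)
                ci = int(np.nanargmax(np.abs(z)))
                if abs(z[ci]) <= z_threshold:
                    break
                sub[ri, ci] = np.nan
                vals[ri, pos[ci]] = np.nan
                flagged.append((out.index[ri], cols[ci]))
                removed += 1
    out.iloc[:, :] = vals
    return out, flagged


# ---------------------------------------------------------------------------
# Invariance filter
# ---------------------------------------------------------------------------

def filter_invariant_peaks(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove peaks invariant among populations (Kruskal-Wallis on
    genotype-level replicate medians, p > ``alpha``).

    Constant peaks (no variation at all) have p defined as 1 and are
    removed — the filter's purpose is to retain biological contrast.
    """
    from .stats import median_by_genotype

    meta_exp = _experimental(meta)
    if meta_exp["population"].nunique() < 2:
        raise ValueError("invariance filter needs >= 2 populations")
    gmat, gpop = median_by_genotype(matrix, meta)
    pops = pd.unique(gpop)
    for p in pops:
        if (gpop == p).sum() == 0:  # pragma: no cover
            raise ValueError(f"population {p!r} has no genotypes")
    masks = [gpop == p for p in pops]
    vals = gmat.to_numpy(dtype=float)
    ps = np.ones(vals.shape[0])
    for i in range(vals.shape[0]):
        groups = [vals[i, m] for m in masks]
        groups = [g[~np.isnan(g)] for g in groups]
        groups = [g for g in groups if len(g) >= 1]
        if len(groups) < 2:
            continue
        flat = np.concatenate(groups)
        if np.allclose(flat, flat[0]):
            continue
        try:
            _, p = sps.kruskal(*groups)
        except ValueError:  # all values identical
            p = 1.0
        ps[i] = 1.0 if np.isnan(p) else p
    pser = pd.Series(ps, index=matrix.index, name="kruskal_p")
    return matrix.loc[ps <= alpha], pser


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------

def pca_qc(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the log, peak-centered matrix.

    Returns (scores per sample with metadata labels, variance-explained
    fractions, non-increasing and summing to <= 1).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA QC needs >= 3 samples")
    from sklearn.decomposition import PCA

    X = _log(matrix).T  # samples x peaks
    X = X - X.mean(axis=0, keepdims=True)
    k = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    meta_idx = meta.set_index("sample_id").loc[matrix.columns]
    df = pd.DataFrame(scores, index=matrix.columns,
                      columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    df["is_control"] = meta_idx["is_control"].to_numpy(dtype=bool)
    df["population"] = meta_idx["population"].to_numpy()
    return df, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Full QC stage
# ---------------------------------------------------------------------------

@dataclass
class QcLog:
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, criterion: str) -> None:
        self.stages.append({"stage": stage, "peaks_in": n_in,
                            "peaks_out": n_out, "criterion": criterion})


def run_qc(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    ppm_tol: float = 20.0,
    rt_tol: float = 0.2,
    alpha_batch: float = 0.05,
    alpha_invariance: float = 0.05,
    cv_trigger: float = 0.2,
    z_threshold: float = 3.0,
    cv_threshold: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, QcLog, CvReport]:
    """Run the QC stages in their fixed order; returns the filtered matrix,
    the annotation table restricted to survivors, the per-stage log, and
    the replicate-cv report (computed after correction)."""
    log = QcLog()

    n0 = len(matrix)
    matrix, annot, merge_log = merge_duplicate_peaks(matrix, annot, ppm_tol, rt_tol)
    log.record("merge_duplicate_peaks", n0, len(matrix),
               f"|dm/z| <= {ppm_tol} ppm and |drt| <= {rt_tol} min")

    n0 = len(matrix)
    matrix = correct_batch_effects(matrix, meta)
    log.record("correct_batch_effects", n0, len(matrix),
               "parametric EB location/scale adjustment on log intensity")

    n0 = len(matrix)
    matrix, _ = filter_residual_batch(matrix, meta, alpha_batch)
    log.record("filter_residual_batch", n0, len(matrix),
               f"one-way batch ANOVA p < {alpha_batch} removed")

    cv_report = replicate_cv(matrix, meta, cv_threshold)

    n0 = len(matrix)
    matrix, flagged = remove_replicate_outliers(matrix, meta, cv_trigger, z_threshold)
    log.record("remove_replicate_outliers", n0, len(matrix),
               f"cv > {cv_trigger} groups, |modified Z| > {z_threshold} blanked "
               f"({len(flagged)} cells)")

    n0 = len(matrix)
    matrix, _ = filter_invariant_peaks(matrix, meta, alpha_invariance)
    log.record("filter_invariant_peaks", n0, len(matrix),
               f"Kruskal-Wallis across populations p > {alpha_invariance} removed")

    annot = annot[annot["peak_id"].isin(matrix.index)].reset_index(drop=True)
    return matrix, annot, log, cv_report
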