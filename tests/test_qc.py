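"""QC filtering: merging, batch correction, outlier removal, invariance."""

import numpy as np
import pandas as pd
import pytest

from grassmet import qc
from grassmet import simulate as sim
from grassmet.combat import combat
from grassmet.reference import direct_combat


def _matrix(values, peak_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    peak_ids = peak_ids or [f"CP{100+i}.0000_1.00" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    m = pd.DataFrame(values, index=peak_ids, columns=sample_ids)
    m.index.name = "peak_id"
    return m


def _meta(sample_ids, batches=None, genotypes=None, populations=None,
          replicates=None, controls=None):
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "population": populations or ["popA"] * n,
        "genotype": genotypes or ["g1"] * n,
        "replicate": replicates or list(range(1, n + 1)),
        "batch": batches or ["b1"] * n,
        "ion_mode": "positive",
        "is_control": controls or [False] * n,
    })


class TestMergeDuplicatePeaks:
    def test_close_pair_merges(self, make_annot):
        annot = make_annot([("CP434.2167_4.58", 434.2167, 4.58),
                            ("CP434.2169_4.58", 434.2169, 4.58)])
        m = _matrix([[10, 20], [30, 5]],
                    peak_ids=["CP434.2167_4.58", "CP434.2169_4.58"])
        out, ann, log = qc.merge_duplicate_peaks(m, annot)
        assert len(out) == 1
        # per-sample maximum retained
        assert out.iloc[0].tolist() == [30, 20]
        assert len(log) == 1

    def test_rt_gap_above_tolerance_not_merged(self, make_annot):
        annot = make_annot([("CP434.2167_4.58", 434.2167, 4.58),
                            ("CP434.2167_4.80", 434.2167, 4.80)])
        m = _matrix([[10, 20], [30, 5]],
                    peak_ids=["CP434.2167_4.58", "CP434.2167_4.80"])
        out, _, log = qc.merge_duplicate_peaks(m, annot)
        assert len(out) == 2 and not log

    def test_empty_table(self, make_annot):
        m = _matrix(np.empty((0, 3)))
        out, _, log = qc.merge_duplicate_peaks(m, make_annot([]))
        assert out.empty and not log

    def test_idempotent(self, default_run):
        m1, a1, _ = qc.merge_duplicate_peaks(default_run["matrix"],
                                             default_run["annot"])
        m2, a2, log2 = qc.merge_duplicate_peaks(m1, a1)
        assert not log2
        pd.testing.assert_frame_equal(m1, m2)


class TestBatchCorrection:
    def test_matches_direct_implementation_to_1e8(self):
        rng = np.random.default_rng(3)
        X = rng.normal(12, 1, size=(25, 18))
        batch = np.repeat(["b1", "b2", "b3"], 6)
        X[:, batch == "b2"] += rng.normal(1.0, 0.4, 25)[:, None]
        assert np.max(np.abs(combat(X, batch) - direct_combat(X, batch))) < 1e-8

    def test_scanpy_combat_cross_check(self):
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(5)
        X = rng.normal(10, 1, size=(40, 30))
        batch = np.repeat(["b1", "b2", "b3"], 10)
        X[:, batch == "b3"] += 0.9
        mine = combat(X, batch)
        ad = anndata.AnnData(X.T.copy())
        ad.obs["batch"] = batch
        sc.pp.combat(ad, key="batch")
        assert np.max(np.abs(mine - ad.X.T)) < 0.05

    def test_removes_injected_batch_shifts(self, default_run):
        matrix, meta = default_run["matrix"], default_run["meta"]
        corrected = qc.correct_batch_effects(matrix, meta)
        _, ps = qc.filter_residual_batch(corrected, meta)
        full = [pid for pid in matrix.index if (matrix.loc[pid] > 2e3).all()]
        assert (ps.loc[full] < 0.05).mean() <= 0.07

    def test_null_data_nearly_unchanged(self):
        rng = np.random.default_rng(9)
        vals = np.exp(rng.normal(12, 1, size=(30, 24)))
        m = _matrix(vals)
        meta = _meta(list(m.columns), batches=["b1"] * 12 + ["b2"] * 12)
        out = qc.correct_batch_effects(m, meta)
        rel = np.abs(np.log(out.to_numpy() + 1) - np.log(vals + 1))
        assert np.median(rel) < 0.2  # adjustments stay at noise level

    def test_small_batch_raises_naming_batch(self):
        m = _matrix(np.ones((5, 3)) * 100)
        meta = _meta(list(m.columns), batches=["b1", "b1", "b2"])
        with pytest.raises(ValueError, match="b2"):
            qc.correct_batch_effects(m, meta)


class TestResidualBatchFilter:
    def test_huge_shift_removed_constant_retained(self):
        rng = np.random.default_rng(2)
        shifted = np.concatenate([rng.normal(1e4, 100, 10),
                                  rng.normal(1e6, 100, 10)])
        const = np.full(20, 5e5)
        m = _matrix([shifted, const])
        meta = _meta(list(m.columns), batches=["b1"] * 10 + ["b2"] * 10)
        out, ps = qc.filter_residual_batch(m, meta)
        assert ps.iloc[0] < 0.05 and ps.iloc[1] == 1.0
        assert list(out.index) == [m.index[1]]

    def test_type_one_error_calibration_on_null(self):
        rng = np.random.default_rng(4)
        n_peaks = 500
        vals = np.exp(rng.normal(12, 0.5, size=(n_peaks, 36)))
        m = _matrix(vals)
        meta = _meta(list(m.columns), batches=list(np.repeat(
            ["b1", "b2", "b3"], 12)))
        _, ps = qc.filter_residual_batch(m, meta)
        frac = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_peaks)
        assert abs(frac - 0.05) <= 3 * se


class TestReplicateCv:
    def test_hand_computed_values(self):
        m = _matrix([[100, 100, 100, 100, 100],
                     [80, 100, 120, np.nan, np.nan]])
        meta = _meta(list(m.columns), genotypes=["g1"] * 5,
                     replicates=[1, 2, 3, 4, 5])
        rep = qc.replicate_cv(m, meta)
        assert rep.per_genotype.iloc[0, 0] == 0.0
        assert rep.per_genotype.iloc[1, 0] == pytest.approx(0.2)

    def test_single_replicate_cell_excluded(self):
        m = _matrix([[100, 50, np.nan]])
        meta = _meta(list(m.columns), genotypes=["g1", "g1", "g2"],
                     replicates=[1, 2, 1])
        rep = qc.replicate_cv(m, meta)
        assert np.isnan(rep.per_genotype.loc[m.index[0], "g2"])
        assert rep.median_cv.iloc[0] == rep.per_genotype.loc[m.index[0], "g1"]

    def test_recovers_generator_noise_level(self, clean_run):
        rep = qc.replicate_cv(clean_run["matrix"], clean_run["meta"])
        truth = clean_run["truth"]
        present = [pid for pid, mem in truth.row_members.items()
                   if all(min(truth.metabolites_by_name[n]
                              .population_presence.values()) > 0
                          for n, _, _ in mem)]
        assert 0.15 <= rep.median_cv.loc[present].median() <= 0.25


class TestModifiedZscore:
    def test_hand_computed_outlier(self):
        z = qc.modified_zscore(np.array([1, 2, 3, 4, 100]))
        assert z[-1] == pytest.approx(0.6745 * 97)
        assert z[2] == 0.0  # the median itself

    def test_constant_vector_all_zero(self):
        assert np.all(qc.modified_zscore(np.array([5.0, 5.0, 5.0])) == 0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            qc.modified_zscore(np.array([]))


class TestOutlierRemoval:
    def test_hand_example_removes_extreme(self):
        m = _matrix([[100, 101, 99, 100, 500]])
        meta = _meta(list(m.columns), genotypes=["g1"] * 5,
                     replicates=[1, 2, 3, 4, 5])
        out, flagged = qc.remove_replicate_outliers(m, meta)
        assert np.isnan(out.iloc[0, 4])
        assert flagged == [(m.index[0], "s4")]

    def test_low_cv_group_untouched(self):
        m = _matrix([[100, 102, 98, 101, 110]])  # cv ~ 0.045
        meta = _meta(list(m.columns), genotypes=["g1"] * 5,
                     replicates=[1, 2, 3, 4, 5])
        out, flagged = qc.remove_replicate_outliers(m, meta)
        assert not flagged and not out.isna().any().any()

    def test_at_most_half_removed(self):
        m = _matrix([[1, 1, 1000, 2000, 3000, 4000]])
        meta = _meta(list(m.columns), genotypes=["g1"] * 6,
                     replicates=list(range(1, 7)))
        out, flagged = qc.remove_replicate_outliers(m, meta)
        assert len(flagged) <= 3

    def test_idempotent_on_survey_data(self, default_run):
        corrected = qc.correct_batch_effects(default_run["matrix"],
                                             default_run["meta"])
        once, _ = qc.remove_replicate_outliers(corrected, default_run["meta"])
        twice, flagged2 = qc.remove_replicate_outliers(once, default_run["meta"])
        assert not flagged2

    def test_recovers_injected_outliers(self, default_run):
        truth, meta = default_run["truth"], default_run["meta"]
        corrected = qc.correct_batch_effects(default_run["matrix"], meta)
        _, flagged = qc.remove_replicate_outliers(corrected, meta)
        flagged_set = {(s, p) for p, s in flagged}
        injected = set(truth.injected_outliers)
        sensitivity = len(flagged_set & injected) / len(injected)
        n_cells = corrected.size
        false_rate = len(flagged_set - injected) / (n_cells - len(injected))
        assert sensitivity >= 0.9
        assert false_rate <= 0.05


class TestInvarianceFilter:
    def test_constant_peak_removed_contrast_retained(self):
        rng = np.random.default_rng(6)
        n = 30  # 3 populations x 5 genotypes x 2 reps
        pops = np.repeat(["pA", "pB", "pC"], 10)
        genos = [f"g{i//2}" for i in range(n)]
        flat = np.full(n, 1e5)
        contrast = np.where(pops == "pA", 1e6, 1e3) * rng.lognormal(0, 0.05, n)
        m = _matrix([flat, contrast])
        meta = _meta([f"s{j}" for j in range(n)], genotypes=genos,
                     populations=list(pops), replicates=[1, 2] * 15)
        out, ps = qc.filter_invariant_peaks(m, meta)
        assert m.index[0] not in out.index
        assert m.index[1] in out.index

    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(8)
        n_peaks, n = 400, 60
        pops = np.repeat([f"p{i}" for i in range(6)], 10)
        genos = [f"g{i//2}" for i in range(n)]
        vals = np.exp(rng.normal(12, 0.5, size=(n_peaks, n)))
        m = _matrix(vals, sample_ids=[f"s{j}" for j in range(n)])
        meta = _meta(list(m.columns), genotypes=genos, populations=list(pops),
                     replicates=[1, 2] * 30)
        out, _ = qc.filter_invariant_peaks(m, meta)
        frac = len(out) / n_peaks
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_peaks)

    def test_single_population_raises(self):
        m = _matrix([[1, 2, 3, 4]])
        meta = _meta(list(m.columns), genotypes=["g1", "g1", "g2", "g2"],
                     replicates=[1, 2, 1, 2])
        with pytest.raises(ValueError):
            qc.filter_invariant_peaks(m, meta)


class TestPcaQc:
    def test_variance_fractions_shape(self, default_run):
        scores, var = qc.pca_qc(default_run["matrix"], default_run["meta"])
        assert len(var) >= 2
        assert np.all(np.diff(var) <= 1e-12)
        assert np.all((0 <= var) & (var <= 1)) and var.sum() <= 1 + 1e-9

    def test_rank_one_matrix_single_component(self):
        # log(x + 1) separable in peak + sample terms -> rank 1 after centering
        peak_term = np.linspace(8, 10, 5)
        sample_term = np.linspace(0, 2, 8)
        u = np.exp(peak_term[:, None] + sample_term[None, :]) - 1.0
        m = _matrix(u)
        meta = _meta(list(m.columns))
        _, var = qc.pca_qc(m, meta)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_controls_separate_from_samples(self, default_run):
        corrected = qc.correct_batch_effects(default_run["matrix"],
                                             default_run["meta"])
        scores, _ = qc.pca_qc(corrected, default_run["meta"])
        pcs = scores[["PC1", "PC2"]].to_numpy()
        ctrl = scores["is_control"].to_numpy(dtype=bool)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(pcs, ctrl) > 0

    def test_too_few_samples(self):
        m = _matrix(np.ones((4, 2)))
        with pytest.raises(ValueError):
            qc.pca_qc(m, _meta(list(m.columns)))


class TestRunQc:
    def test_filters_only_remove_rows_or_blank_cells(self, default_run):
        """Every stage except batch correction leaves surviving
        intensities untouched."""
        matrix, annot, meta = (default_run["matrix"], default_run["annot"],
                               default_run["meta"])
        m1, _, _ = qc.merge_duplicate_peaks(matrix, annot)
        m2 = qc.correct_batch_effects(m1, meta)
        m3, _ = qc.filter_residual_batch(m2, meta)
        assert np.allclose(m2.loc[m3.index], m3, equal_nan=True)
        m4, flagged = qc.remove_replicate_outliers(m3, meta)
        kept = m4.notna()
        assert np.allclose(m3[kept].to_numpy(), m4[kept].to_numpy(),
                           equal_nan=True)
        m5, _ = qc.filter_invariant_peaks(m4, meta)
        assert np.allclose(m4.loc[m5.index], m5, equal_nan=True)

    def test_rerun_on_own_output_is_stable(self, default_run):
        matrix, annot, meta = (default_run["matrix"], default_run["annot"],
                               default_run["meta"])
        m1, a1, log1, _ = qc.run_qc(matrix, annot, meta)
        m2, a2, log2, _ = qc.run_qc(m1, a1, meta)
        # merging and the hard filters find nothing new; the second EB pass
        # applies a vanishing adjustment that may flip a borderline p-value,
        # so allow at most 2% of rows to change status
        by_stage = {s["stage"]: s for s in log2.stages}
        assert by_stage["merge_duplicate_peaks"]["peaks_in"] == \
               by_stage["merge_duplicate_peaks"]["peaks_out"]
        assert len(m2) >= 0.95 * len(m1)
        # surviving intensities barely move; restrict to fully detected
        # rows — the EB location/scale model is ill-posed for rows that mix
        # detected signal with fill-in floor values
        full = [pid for pid in m2.index if (m1.loc[pid].dropna() > 2e3).all()]
        a = np.log(m1.loc[full].to_numpy(dtype=float) + 1)
        b = np.log(m2.loc[full].to_numpy(dtype=float) + 1)
        ok = ~(np.isnan(a) | np.isnan(b))
        diff = np.abs(a[ok] - b[ok])
        assert np.median(diff) < 0.05
        assert np.quantile(diff, 0.99) < 0.25
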