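"""Population-level differential mining: moderated test, ranking, UPGMA,
peak aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from grassmet import stats as st
from grassmet.reference import brute_force_upgma, merges_from_linkage


def _meta(sample_ids, genotypes, populations, replicates=None, controls=None):
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "population": populations,
        "genotype": genotypes,
        "replicate": replicates or [1] * n,
        "batch": ["b1"] * n,
        "ion_mode": "positive",
        "is_control": controls or [False] * n,
    })


class TestMedianByGenotype:
    def test_hand_examples(self):
        m = pd.DataFrame([[10, 20, 30, 40, 50],
                          [10, 20, np.nan, 40, 50],
                          [7, np.nan, np.nan, np.nan, np.nan]],
                         index=["p1", "p2", "p3"],
                         columns=[f"s{j}" for j in range(5)])
        meta = _meta(list(m.columns), ["g1"] * 5, ["popA"] * 5,
                     replicates=[1, 2, 3, 4, 5])
        gmat, gpop = st.median_by_genotype(m, meta)
        assert gmat.loc["p1", "g1"] == 30
        assert gmat.loc["p2", "g1"] == 30  # median of 4 values
        assert gmat.loc["p3", "g1"] == 7   # single replicate

    def test_controls_excluded(self):
        m = pd.DataFrame([[10, 20, 999]], index=["p1"],
                         columns=["s0", "s1", "c0"])
        meta = _meta(list(m.columns), ["g1", "g1", "control"],
                     ["popA", "popA", "control"], replicates=[1, 2, 1],
                     controls=[False, False, True])
        gmat, _ = st.median_by_genotype(m, meta)
        assert list(gmat.columns) == ["g1"]
        assert gmat.loc["p1", "g1"] == 15


# limma (bioconductor-limma 3.58.1) moderated-F oracle on the fixture
# below: lmFit(log matrix, model.matrix(~population)) |> eBayes(), with
# topTable over the two population coefficients. Values frozen verbatim.
LIMMA_D0 = 2.34842545
LIMMA_S0_2 = 0.1329165856
LIMMA_F = [9.32132707, 14.48165072, 24.66430573, 3.75100405, 0.29563121,
           0.20148150, 4.22812461, 2.67350910, 1.51008652, 1.97968617,
           5.83127288, 0.34943386]
LIMMA_P = [4.028670e-03, 7.522631e-04, 7.390427e-05, 5.616742e-02,
           7.496211e-01, 5.282707e-01, 4.244174e-02, 1.118531e-01,
           2.621280e-01, 1.830131e-01, 1.811425e-02, 7.124136e-01]


def _limma_fixture():
    rng = np.random.default_rng(42)
    n_peaks, k, g = 12, 3, 4
    sds = np.exp(rng.normal(-0.5, 0.6, n_peaks))
    logx = 10 + rng.normal(size=(n_peaks, k * g)) * sds[:, None]
    logx[:3, 4:8] += np.array([1.5, 0.8, 2.0])[:, None]
    gm = pd.DataFrame(np.exp(logx) - 1.0,
                      index=[f"p{i}" for i in range(n_peaks)],
                      columns=[f"g{i}" for i in range(k * g)])
    gpop = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=gm.columns)
    return gm, gpop


class TestModeratedTest:
    def test_matches_limma_oracle(self):
        gm, gpop = _limma_fixture()
        res = st.moderated_population_test(gm, gpop)
        assert res.attrs["prior_df"] == pytest.approx(LIMMA_D0, abs=1e-6)
        assert res.attrs["prior_s2"] == pytest.approx(LIMMA_S0_2, rel=1e-6)
        np.testing.assert_allclose(res["F"], LIMMA_F, rtol=1e-6)

    def test_zero_prior_weight_equals_classical_anova(self):
        gm, gpop = _limma_fixture()
        res = st.moderated_population_test(gm, gpop, prior_df=0)
        logx = np.log(gm.to_numpy() + 1.0)
        for i, pid in enumerate(gm.index):
            groups = [logx[i, (gpop == p).to_numpy()] for p in ("A", "B", "C")]
            f_ref, p_ref = sps.f_oneway(*groups)
            assert res.loc[pid, "F"] == pytest.approx(f_ref, abs=1e-10)
            assert res.loc[pid, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_identical_population_means_give_zero_f(self):
        vals = np.tile([[100.0, 100.0, 100.0, 100.0, 100.0, 100.0]], (2, 1))
        gm = pd.DataFrame(vals, index=["p1", "p2"],
                          columns=[f"g{i}" for i in range(6)])
        gpop = pd.Series(["A"] * 3 + ["B"] * 3, index=gm.columns)
        res = st.moderated_population_test(gm, gpop)
        assert (res["F"] == 0).all()
        assert (res["p"] == 1).all()

    def test_bh_adjustment_monotone(self):
        gm, gpop = _limma_fixture()
        res = st.moderated_population_test(gm, gpop)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["p_adj"].between(0, 1).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["p_adj"]) >= -1e-12).all()

    def test_truth_recovery_with_fdr_control(self, default_run):
        """On the merged, batch-corrected table (the substrate the test
        runs on in the pipeline), all truly differential metabolites reach
        adjusted p < 0.01 and invariant peaks rarely do."""
        from grassmet.qc import correct_batch_effects, merge_duplicate_peaks
        truth, meta = default_run["truth"], default_run["meta"]
        matrix, annot, _ = merge_duplicate_peaks(default_run["matrix"],
                                                 default_run["annot"])
        matrix = correct_batch_effects(matrix, meta)
        gmat, gpop = st.median_by_genotype(matrix, meta)
        res = st.moderated_population_test(gmat, gpop)
        diff_names = set(truth.differential_names())
        null_hits, null_total = 0, 0
        diff_metabolites_hit = set()
        for pid in res.index:
            names = {n for n, _, _ in truth.row_members[pid]}
            sig = res.loc[pid, "p_adj"] < 0.01
            if names & diff_names:
                if sig:
                    diff_metabolites_hit |= names & diff_names
            elif all(truth.metabolites_by_name[n].n_isomer_splits == 1
                     for n in names):
                null_total += 1
                null_hits += sig
        assert len(diff_metabolites_hit) == len(diff_names)
        assert null_hits / null_total < 0.02


class TestRankTopPeaks:
    def _result(self):
        rng = np.random.default_rng(0)
        n = 120
        return pd.DataFrame({
            "F": rng.exponential(5, n),
            "p": rng.uniform(size=n),
            "p_adj": rng.uniform(size=n),
            "mean_intensity": 10 ** rng.uniform(4, 7, n),
        }, index=[f"CP{400 + i}.0000_1.00" for i in range(n)])

    def test_gate_and_k(self):
        res = self._result()
        top = st.rank_top_peaks(res, intensity_min=1e5, k=20)
        assert len(top) == 20
        assert (top["mean_intensity"] > 1e5).all()
        assert (np.diff(top["F"]) <= 1e-12).all()
        assert list(top["rank"]) == list(range(1, 21))

    def test_k_larger_than_gated(self):
        res = self._result()
        n_gated = int((res["mean_intensity"] > 1e6).sum())
        with pytest.warns(UserWarning):
            top = st.rank_top_peaks(res, intensity_min=1e6, k=1000)
        assert len(top) == n_gated

    def test_row_order_invariance(self):
        res = self._result()
        top1 = st.rank_top_peaks(res, k=30)
        shuffled = res.sample(frac=1, random_state=5)
        top2 = st.rank_top_peaks(shuffled, k=30)
        assert list(top1.index) == list(top2.index)


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        prof = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["A", "B"])
        tree, Z, labels = st.upgma(prof)
        assert Z[0, 2] == pytest.approx(5.0)
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(2.5)
        assert tips["B"].length == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_leaves", [4, 6, 8])
    def test_matches_merge_step_oracle(self, seed, n_leaves):
        rng = np.random.default_rng(seed * 100 + n_leaves)
        prof = pd.DataFrame(rng.normal(size=(n_leaves, 12)),
                            index=[f"L{i}" for i in range(n_leaves)])
        _, Z, _ = st.upgma(prof)
        fast = merges_from_linkage(Z, n_leaves)
        slow = brute_force_upgma(squareform(pdist(prof.to_numpy())))
        assert len(fast) == len(slow)
        for (hf, mf), (hs, ms) in zip(fast, slow):
            assert hf == pytest.approx(hs, rel=1e-10)
            assert mf == ms

    def test_trees_are_ultrametric(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(7, 20)),
                            index=[f"L{i}" for i in range(7)])
        tree, _, _ = st.upgma(prof)
        depths = [tree.distance(t) for t in tree.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_newick_export_round_trips(self, tmp_path):
        from skbio import TreeNode
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(5, 9)),
                            index=[f"P{i}" for i in range(5)])
        tree, _, _ = st.upgma(prof)
        path = tmp_path / "t.nwk"
        tree.write(str(path))
        back = TreeNode.read(str(path))
        assert {t.name for t in back.tips()} == {f"P{i}" for i in range(5)}

    def test_shared_signature_populations_are_sisters(self, default_run):
        """The two populations sharing the presence/absence signature
        cluster together, apart from all others."""
        profiles = st.population_profiles(default_run["matrix"],
                                          default_run["meta"])
        tree, _, _ = st.upgma(profiles)
        lca = tree.lca(["PG238", "Tunisia"])
        assert {t.name for t in lca.tips()} == {"PG238", "Tunisia"}


class TestAggregation:
    def test_split_conserves_aggregate_exactly(self, make_annot):
        rng = np.random.default_rng(2)
        v = rng.uniform(1e4, 1e6, 10)
        annot = make_annot([("CP353.0870_4.00", 353.0870, 4.00),
                            ("CP353.0875_4.20", 353.0875, 4.20)])
        m = pd.DataFrame([v * 0.4, v * 0.6],
                         index=["CP353.0870_4.00", "CP353.0875_4.20"],
                         columns=[f"s{j}" for j in range(10)])
        m.index.name = "peak_id"
        whole = pd.DataFrame([v], index=["CP353.0870_4.00"],
                             columns=m.columns)
        whole.index.name = "peak_id"
        agg_split = st.aggregate_isomeric_peaks(m, annot, 353.0867, 10.0)
        agg_whole = st.aggregate_isomeric_peaks(
            whole, make_annot([("CP353.0870_4.00", 353.0870, 4.00)]),
            353.0867, 10.0)
        np.testing.assert_array_equal(agg_split.aggregate.to_numpy(),
                                      agg_whole.aggregate.to_numpy())
        # exact member sum, per sample
        np.testing.assert_array_equal(
            agg_split.aggregate.to_numpy(),
            m.loc[agg_split.member_peaks].sum(axis=0).to_numpy())

    def test_ppm_window_boundaries(self, make_annot):
        annot = make_annot([("CP353.0875_5.39", 353.0875, 5.39),
                            ("CP353.1000_5.39", 353.1000, 5.39)])
        m = pd.DataFrame(np.ones((2, 4)),
                         index=["CP353.0875_5.39", "CP353.1000_5.39"],
                         columns=[f"s{j}" for j in range(4)])
        m.index.name = "peak_id"
        res = st.aggregate_isomeric_peaks(m, annot, 353.0867, 10.0)
        assert res.member_peaks == ["CP353.0875_5.39"]  # 2.3 ppm in, 38 ppm out

    def test_missing_treated_as_zero(self, make_annot):
        annot = make_annot([("CP400.0000_3.00", 400.0, 3.0),
                            ("CP400.0010_3.20", 400.001, 3.2)])
        m = pd.DataFrame([[10.0, np.nan], [np.nan, 5.0]],
                         index=["CP400.0000_3.00", "CP400.0010_3.20"],
                         columns=["s0", "s1"])
        m.index.name = "peak_id"
        res = st.aggregate_isomeric_peaks(m, annot, 400.0005, 10.0)
        assert res.aggregate.tolist() == [10.0, 5.0]

    def test_empty_window_is_notice_not_error(self, make_annot):
        annot = make_annot([("CP400.0000_3.00", 400.0, 3.0)])
        m = pd.DataFrame([[1.0]], index=["CP400.0000_3.00"], columns=["s0"])
        m.index.name = "peak_id"
        res = st.aggregate_isomeric_peaks(m, annot, 800.0, 10.0)
        assert res.member_peaks == [] and res.notice

    def test_misalignment_scenario_recovers_invariance(self):
        """Split isomer rows of an invariant metabolite test significant
        under the naive per-row analysis, while the RT-windowed aggregate
        tested at the genotype level does not."""
        from grassmet.scenarios import cga_misalignment
        rep = cga_misalignment(seed=0, n_runs=5)
        assert rep["aggregate_p_median"] > 0.05
        assert rep["min_member_p_median"] < 0.05
        assert rep["n_member_rows_median"] > 1
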