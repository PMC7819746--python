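"""Z-score and fuzzy-clustering enrichment calling and consistency tiers."""
import numpy as np
import pandas as pd
import pytest

from mirenrich import enrichment as en
from mirenrich import preprocessing as pp
from mirenrich.io_formats import CELL_TYPES, SampleSheet

from oracles import fcm_multistart_best_objective


def _sheet_one_condition(n_per_ct=4, condition="sham"):
    rows = [{"sample_id": f"{ct}_{condition}_r{r}", "cell_type": ct,
             "condition": condition, "replicate": r}
            for ct in CELL_TYPES for r in range(1, n_per_ct + 1)]
    return SampleSheet(pd.DataFrame(rows))


class TestZscore:
    def test_hand_computed_row(self, small_logcpm, small_dataset):
        # sample-SD (n-1) convention: [1,2,3] -> [-1, 0, 1]
        _, sheet, _ = small_dataset
        ids = sheet.samples_for(condition="sham")[:3]
        from mirenrich.preprocessing import NormalizedMatrix
        mat = NormalizedMatrix(["m"], ids, np.array([[1.0, 2.0, 3.0]]),
                               np.ones(3), log_base="log2")
        sub = sheet.subset(ids)
        z = en.zscore_by_condition(mat, sub, "sham")
        np.testing.assert_allclose(z.z[0], [-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_and_flagged(self, small_dataset):
        _, sheet, _ = small_dataset
        ids = sheet.samples_for(condition="sham")
        from mirenrich.preprocessing import NormalizedMatrix
        mat = NormalizedMatrix(["flat", "var"], ids,
                               np.vstack([np.full(len(ids), 5.0),
                                          np.arange(len(ids), dtype=float)]),
                               np.ones(len(ids)), log_base="log2")
        z = en.zscore_by_condition(mat, sheet, "sham")
        assert z.constant_rows == ["flat"]
        np.testing.assert_allclose(z.z[0], 0.0)

    def test_standardization_identity(self, small_logcpm, small_dataset):
        _, sheet, _ = small_dataset
        z = en.zscore_by_condition(small_logcpm, sheet, "UUO2")
        np.testing.assert_allclose(z.z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_missing_condition_errors(self, small_logcpm, small_dataset):
        _, sheet, _ = small_dataset
        with pytest.raises(ValueError, match="nonesuch"):
            en.zscore_by_condition(small_logcpm, sheet, "nonesuch")


class TestMeanCelltypeZ:
    def test_matches_groupby_and_weighted_zero(self, small_logcpm, small_dataset):
        _, sheet, _ = small_dataset
        z = en.zscore_by_condition(small_logcpm, sheet, "sham")
        mean_z = en.mean_celltype_zscores(z, sheet)
        zdf = z.to_frame()
        ct_of = sheet.cell_type_of()
        brute = zdf.T.groupby(ct_of.loc[zdf.columns]).mean().T[list(CELL_TYPES)]
        pd.testing.assert_frame_equal(mean_z, brute, check_names=False)
        # sum of n_ct * mean_ct recovers the all-sample zero sum
        n_ct = ct_of.loc[zdf.columns].value_counts()
        weighted = sum(mean_z[ct] * n_ct[ct] for ct in CELL_TYPES)
        np.testing.assert_allclose(weighted, 0.0, atol=1e-8)

    def test_single_sample_group_equals_its_z(self):
        sheet = _sheet_one_condition(n_per_ct=1)
        from mirenrich.preprocessing import NormalizedMatrix
        ids = sheet.sample_ids
        mat = NormalizedMatrix(["m"], ids, np.array([[1.0, 5.0, 2.0, 4.0]]),
                               np.ones(4), log_base="log2")
        z = en.zscore_by_condition(mat, sheet, "sham")
        mean_z = en.mean_celltype_zscores(z, sheet)
        np.testing.assert_allclose(mean_z.loc["m"].to_numpy(), z.z[0])


class TestZscoreEnriched:
    def test_exact_threshold_excluded(self):
        mean_z = pd.DataFrame({"PT": [1.15], "Mac": [1.1500000001],
                               "EC": [0.0], "PDGFRB": [-1.0]}, index=["m"])
        sets = en.zscore_enriched(mean_z, threshold=1.15)
        assert "m" not in sets["PT"]       # strictly 'more than'
        assert "m" in sets["Mac"]

    def test_single_winner_vector(self):
        mean_z = pd.DataFrame([[2.0, -0.6, -0.7, -0.7]], index=["m"],
                              columns=list(CELL_TYPES))
        sets = en.zscore_enriched(mean_z)
        assert sets == {"PT": {"m"}, "Mac": set(), "EC": set(), "PDGFRB": set()}

    def test_matches_comprehension(self, rng):
        mean_z = pd.DataFrame(rng.normal(size=(50, 4)),
                              index=[f"m{i}" for i in range(50)],
                              columns=list(CELL_TYPES))
        sets = en.zscore_enriched(mean_z, threshold=0.8)
        for ct in CELL_TYPES:
            assert sets[ct] == {m for m in mean_z.index
                                if mean_z.loc[m, ct] > 0.8}

    def test_threshold_monotone(self, rng):
        mean_z = pd.DataFrame(rng.normal(size=(50, 4)),
                              index=[f"m{i}" for i in range(50)],
                              columns=list(CELL_TYPES))
        lo = en.zscore_enriched(mean_z, threshold=0.5)
        hi = en.zscore_enriched(mean_z, threshold=1.5)
        assert all(hi[ct] <= lo[ct] for ct in CELL_TYPES)


class TestFuzzyCmeans:
    def _blobs(self, rng, n=30):
        a = rng.normal([0, 0], 0.2, (n, 2))
        b = rng.normal([8, 8], 0.2, (n, 2))
        return np.vstack([a, b])

    def test_separated_blobs_crisp(self, rng):
        X = self._blobs(rng)
        model = en.fuzzy_cmeans(X, c=2, m=1.18, seed=3)
        assert (model.membership.max(axis=1) > 0.99).all()

    def test_objective_trace_non_increasing(self, rng):
        X = rng.normal(size=(40, 5))
        model = en.fuzzy_cmeans(X, c=4, m=1.5, seed=1, n_restarts=1)
        assert (np.diff(model.objective_trace) <= 1e-9).all()

    def test_memberships_sum_to_one(self, rng):
        model = en.fuzzy_cmeans(rng.normal(size=(25, 3)), c=5, m=1.18, seed=2)
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_coincident_point_full_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        model = en.fuzzy_cmeans(X, c=2, m=1.18, seed=0, n_restarts=3)
        assert (model.membership.max(axis=1) > 1 - 1e-9).all()

    def test_tiny_instance_matches_multistart_oracle(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0],
                      [10.0, 10.0], [10.0, 11.0], [11.0, 10.0]])
        model = en.fuzzy_cmeans(X, c=2, m=1.18, seed=5, tol=1e-10)
        best = fcm_multistart_best_objective(X, c=2, m=1.18,
                                             n_restarts=5000, seed=9)
        assert model.objective_trace[-1] == pytest.approx(best, abs=1e-6)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 4))
        a = en.fuzzy_cmeans(X, c=3, m=1.18, seed=7)
        b = en.fuzzy_cmeans(X, c=3, m=1.18, seed=7)
        np.testing.assert_array_equal(a.membership, b.membership)

    def test_invalid_params(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            en.fuzzy_cmeans(X, c=1)
        with pytest.raises(ValueError):
            en.fuzzy_cmeans(X, c=2, m=1.0)


class TestClusterSelection:
    def _model(self, centroids):
        c = np.asarray(centroids, float)
        return en.FuzzyClusterModel(centroids=c, membership=np.zeros((1, len(c))),
                                    fuzzifier_m=1.18, n_clusters_c=len(c),
                                    objective_trace=[0.0], seed=0)

    def test_single_celltype_cluster_assigned(self):
        sheet = _sheet_one_condition()
        ids = sheet.sample_ids
        cent = np.full(16, -1.0)
        for i, s in enumerate(ids):
            if s.startswith("Mac"):
                cent[i] = 1.0
        chosen = en.select_celltype_clusters(self._model([cent]), sheet,
                                             "sham", ids)
        assert chosen["Mac"] == {0}
        assert all(chosen[ct] == set() for ct in ("PT", "EC", "PDGFRB"))

    def test_two_celltype_cluster_unassigned(self):
        sheet = _sheet_one_condition()
        ids = sheet.sample_ids
        cent = np.full(16, -1.0)
        n_mac = n_pt = 0
        for i, s in enumerate(ids):
            if s.startswith("Mac") and n_mac < 3:
                cent[i] = 1.0
                n_mac += 1
            if s.startswith("PT") and n_pt < 3:
                cent[i] = 1.0
                n_pt += 1
        chosen = en.select_celltype_clusters(self._model([cent]), sheet,
                                             "sham", ids)
        assert all(v == set() for v in chosen.values())

    def test_matches_brute_force_rule(self, rng):
        sheet = _sheet_one_condition()
        ids = sheet.sample_ids
        cents = rng.normal(size=(16, len(ids)))
        chosen = en.select_celltype_clusters(self._model(cents), sheet,
                                             "sham", ids,
                                             min_samples_elevated=3,
                                             max_other_elevated=2)
        ct_of = [s.split("_")[0] for s in ids]
        for k in range(16):
            pos = {ct: sum(cents[k, i] > 0 for i, c in enumerate(ct_of) if c == ct)
                   for ct in CELL_TYPES}
            winners = [ct for ct in CELL_TYPES
                       if pos[ct] >= 3 and all(pos[o] <= 2 for o in CELL_TYPES
                                               if o != ct)]
            for ct in CELL_TYPES:
                assert (k in chosen[ct]) == (winners == [ct])


class TestClusterMembers:
    def _model(self, U):
        U = np.asarray(U, float)
        return en.FuzzyClusterModel(centroids=np.zeros((U.shape[1], 2)),
                                    membership=U, fuzzifier_m=1.18,
                                    n_clusters_c=U.shape[1],
                                    objective_trace=[0.0], seed=0)

    def test_argmax_above_cutoff(self):
        sets = en.cluster_member_sets(self._model([[0.9, 0.1]]), ["m"], 0.5)
        assert sets == {0: {"m"}, 1: set()}

    def test_below_cutoff_excluded(self):
        sets = en.cluster_member_sets(self._model([[0.45, 0.55]]), ["m"], 0.6)
        assert sets == {0: set(), 1: set()}

    def test_matches_brute_force(self, rng):
        U = rng.dirichlet(np.ones(4), size=30)
        ids = [f"m{i}" for i in range(30)]
        sets = en.cluster_member_sets(self._model(U), ids, 0.4)
        for i, mid in enumerate(ids):
            k = int(np.argmax(U[i]))
            for kk in range(4):
                assert (mid in sets[kk]) == (kk == k and U[i, k] >= 0.4)


class TestIntersect:
    def test_both_routes_agree(self):
        col = en.intersect_enrichment({"Mac": {"m"}}, {"Mac": {"m"}}, ["m"])
        assert col.loc["m", "assigned_cell"] == "Mac"
        assert col.loc["m", "via_cluster"] and col.loc["m", "via_zscore"]

    def test_two_celltypes_not_cell_specific(self):
        col = en.intersect_enrichment({"Mac": {"m"}, "EC": {"m"}},
                                      {"Mac": {"m"}, "EC": {"m"}}, ["m"])
        assert col.loc["m", "assigned_cell"] == en.NOT_CELL_SPECIFIC

    def test_single_route_unassigned(self):
        col = en.intersect_enrichment({"Mac": {"m"}}, {}, ["m"])
        assert col.loc["m", "assigned_cell"] == en.UNASSIGNED
        assert col.loc["m", "via_cluster"] and not col.loc["m", "via_zscore"]


class TestConsistency:
    @pytest.mark.parametrize("states,tier", [
        (("Mac", "Mac", "Mac", "Mac"), "high"),
        (("Mac", "None", "Mac", "None"), "moderate"),
        (("Mac", "Mac", "Mac", "None"), "moderate"),
        (("Mac", "None", "None", "None"), "low"),
        (("Mac", "None", "PT", "None"), "switching"),
        (("None", "NotCellSpecific", "None", "None"), "none"),
    ])
    def test_tier_rules(self, states, tier):
        df = pd.DataFrame([states], index=["m"],
                          columns=["sham", "UUO2", "UUO7", "RUUO"])
        assert en.consistency_classify(df).loc["m", "tier"] == tier

    def test_tier_algebra(self, rng):
        states = list(CELL_TYPES) + [en.NOT_CELL_SPECIFIC, en.UNASSIGNED]
        df = pd.DataFrame(rng.choice(states, size=(300, 4)),
                          index=[f"m{i}" for i in range(300)],
                          columns=["sham", "UUO2", "UUO7", "RUUO"])
        tiers = en.consistency_classify(df)["tier"]
        ever_single = (df.isin(CELL_TYPES)).any(axis=1).sum()
        counted = tiers.isin(("low", "moderate", "high", "switching")).sum()
        assert counted == ever_single

    def test_missing_condition_errors(self):
        df = pd.DataFrame({"sham": ["Mac"]}, index=["m"])
        with pytest.raises(ValueError):
            en.consistency_classify(df)


class TestTrajectory:
    def test_single_mirna_transitions(self):
        df = pd.DataFrame([["Mac", "Mac", "None", "None"]], index=["m"],
                          columns=["sham", "UUO2", "UUO7", "RUUO"])
        t = en.trajectory_table(df)
        lookup = t.set_index(["step", "from_state", "to_state"])["count"]
        assert lookup[("sham->UUO2", "Mac", "Mac")] == 1
        assert lookup[("UUO2->UUO7", "Mac", "None")] == 1
        assert lookup[("UUO7->RUUO", "None", "None")] == 1

    def test_counts_conserved_per_step(self, rng):
        states = list(CELL_TYPES) + [en.NOT_CELL_SPECIFIC, en.UNASSIGNED]
        df = pd.DataFrame(rng.choice(states, size=(120, 4)),
                          index=[f"m{i}" for i in range(120)],
                          columns=["sham", "UUO2", "UUO7", "RUUO"])
        t = en.trajectory_table(df)
        assert (t.groupby("step")["count"].sum() == 120).all()

    def test_matches_brute_force_pairs(self, rng):
        states = list(CELL_TYPES) + [en.UNASSIGNED]
        df = pd.DataFrame(rng.choice(states, size=(40, 4)),
                          index=[f"m{i}" for i in range(40)],
                          columns=["sham", "UUO2", "UUO7", "RUUO"])
        t = en.trajectory_table(df).set_index(
            ["step", "from_state", "to_state"])["count"]
        for a, b in (("sham", "UUO2"), ("UUO2", "UUO7"), ("UUO7", "RUUO")):
            for mid in df.index:
                key = (f"{a}->{b}", df.loc[mid, a], df.loc[mid, b])
                brute = sum((df[a] == key[1]) & (df[b] == key[2]))
                assert t[key] == brute


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self, rng):
        X = rng.normal(size=(6, 5))
        X[4] = X[1]
        rows, _ = en.heatmap_order(X)
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[1] - pos[4]) == 1

    def test_hand_computed_average_linkage(self):
        # 1-D points 0, 1, 5, 11: merges (0,1), then (5 with {0,1}: d=4.5)
        # vs (11 with 5: d=6) -> {0,1,5} first, 11 last
        X = np.array([[0.0], [1.0], [5.0], [11.0]])
        rows, _ = en.heatmap_order(X)
        assert list(rows) in ([3, 2, 0, 1], [3, 2, 1, 0],
                              [0, 1, 2, 3], [1, 0, 2, 3])

    def test_row_permutation_equivariance(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import pdist
        X = rng.normal(size=(8, 4))
        perm = rng.permutation(8)
        d1 = cophenet(linkage(X, method="average"))
        d2 = cophenet(linkage(X[perm], method="average"))
        np.testing.assert_allclose(sorted(d1), sorted(d2))
        en.heatmap_order(X[perm])    # orders exist for permuted input

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            en.heatmap_order(np.ones((1, 3)))


class TestCallEnrichment:
    def test_deterministic_under_seed(self, small_logcpm, small_dataset):
        _, sheet, _ = small_dataset
        a = en.call_enrichment(small_logcpm, sheet, n_clusters=8, seed=13,
                               n_restarts=2)
        b = en.call_enrichment(small_logcpm, sheet, n_clusters=8, seed=13,
                               n_restarts=2)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.tiers, b.tiers)

    def test_recovers_planted_enrichment(self, small_logcpm, small_dataset):
        _, sheet, truth = small_dataset
        res = en.call_enrichment(small_logcpm, sheet, n_clusters=8, seed=13,
                                 n_restarts=3)
        planted = truth.home_cell.dropna()
        for cond in res.assignments.columns:
            col = res.assignments[cond]
            correct = np.mean([col.get(m) == ct for m, ct in planted.items()])
            assert correct >= 0.85
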