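"""Morphotype models: Ward/Manhattan clustering, LDA, permutation PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from gliamorph import models, stats, synthetic
from gliamorph.models import (
    LDA_PREDICTORS,
    PCA_PARAMETERS,
    StandardizationRequiredError,
    cut_and_identify,
    hca_ward_manhattan,
    lda_train_test,
    linkage_to_newick,
    optimal_k,
    pca_permutation,
    wilks_test,
)


def standardized(df: pd.DataFrame, cols) -> pd.DataFrame:
    return stats.zscore_table(df, columns=list(cols))


def bruteforce_ward_manhattan(x: np.ndarray) -> np.ndarray:
    """Naive agglomeration re-evaluating the Lance-Williams Ward update at
    every step from the initial Manhattan distance matrix."""
    n = x.shape[0]
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    active = {i: (1, i) for i in range(n)}  # id -> (size, linkage index)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active[i][0], active[j][0]
        merges.append((active[i][1], active[j][1], dij, si + sj))
        new_dists = {}
        for k in ids:
            if k in (i, j):
                continue
            sk = active[k][0]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new = np.sqrt(
                ((si + sk) * dik**2 + (sj + sk) * djk**2 - sk * dij**2)
                / (si + sj + sk)
            )
            new_dists[k] = new
        ids = [k for k in ids if k not in (i, j)]
        dist = {kv: v for kv, v in dist.items() if i not in kv and j not in kv}
        for k, v in new_dists.items():
            dist[tuple(sorted((k, next_id)))] = v
        active[next_id] = (si + sj, next_id)
        ids.append(next_id)
        next_id += 1
    z = np.zeros((n - 1, 4))
    for row, (a, b, h, size) in enumerate(merges):
        z[row] = (min(a, b), max(a, b), h, size)
    return z


class TestHCA:
    def test_two_clouds_split_at_top(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-4, 0.3, (10, 3)), rng.normal(4, 0.3, (10, 3))])
        df = standardized(pd.DataFrame(x, columns=["a", "b", "c"]), "abc")
        tree = hca_ward_manhattan(df, columns=["a", "b", "c"])
        lab = fcluster(tree.linkage, t=2, criterion="maxclust")
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
        assert lab[0] != lab[-1]

    def test_requires_standardized_input(self, table1_table):
        with pytest.raises(StandardizationRequiredError):
            hca_ward_manhattan(table1_table)

    def test_matches_bruteforce_ward_recursion(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        tree = hca_ward_manhattan(df, columns=["a", "b", "c"])
        expected = bruteforce_ward_manhattan(x)
        np.testing.assert_allclose(
            np.sort(tree.linkage[:, 2]), np.sort(expected[:, 2]), rtol=1e-9
        )
        # same final merge height and monotone heights
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    def test_equidistant_points_merge_at_equal_heights(self):
        # 3 unit-simplex-like points: all pairwise Manhattan distances equal
        x = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        tree = hca_ward_manhattan(df, columns=["a", "b", "c"])
        assert tree.linkage[0, 2] == pytest.approx(tree.distance_summary["max"])


class TestCutAndIdentify:
    def test_separated_groups_fully_recovered(self):
        rng = np.random.default_rng(1)
        centers = {"CL": -9.0, "PBZ": -3.0, "INT": 3.0, "TUM": 9.0}
        frames = []
        for roi, c in centers.items():
            frames.append(pd.DataFrame({
                "roi": roi, "a": rng.normal(c, 0.2, 15), "b": rng.normal(c, 0.2, 15)
            }))
        df = pd.concat(frames, ignore_index=True)
        z = standardized(df, ["a", "b"])
        cut = cut_and_identify(
            hca_ward_manhattan(z, columns=["a", "b"]), 4, df["roi"].to_numpy()
        )
        assert sorted(cut.identity.values()) == sorted(centers)
        assert all(cut.composition.loc[c, r] == 1.0 for c, r in cut.identity.items())
        assert cut.minority_cells.size == 0

    def test_table1_synthetic_recovers_four_rois(self, table1_table):
        z = stats.zscore_table(table1_table)
        cut = cut_and_identify(hca_ward_manhattan(z), 4, table1_table["roi"].to_numpy())
        assert sorted(cut.identity.values()) == ["CL", "INT", "PBZ", "TUM"]
        assert not cut.ambiguous
        # composition rows sum to one; identity is each row's argmax
        sums = cut.composition.sum(axis=1)
        assert np.allclose(sums, 1.0)
        for cid, roi in cut.identity.items():
            assert cut.composition.loc[cid].idxmax() == roi

    def test_k_one_minority_is_everyone_else(self, table1_table):
        z = stats.zscore_table(table1_table)
        cut = cut_and_identify(hca_ward_manhattan(z), 1, table1_table["roi"].to_numpy())
        modal = cut.identity[1]
        expected = (table1_table["roi"] != modal).sum()
        assert cut.minority_cells.size == expected


class TestOptimalK:
    def test_two_gaussians_select_two(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(-3, 1.0, (40, 4)), rng.normal(3, 1.0, (40, 4))])
        df = pd.DataFrame(x, columns=list("abcd"))
        res = optimal_k(standardized(df, "abcd"), columns=list("abcd"))
        assert res["chosen_k"] == 2
        assert not res["low_confidence"]

    def test_pbz_cluster_mixture_selects_two(self):
        hits = 0
        for seed in range(20):
            table = synthetic.generate_feature_table(
                synthetic.PBZ_CLUSTER_SPECS, seed=seed
            )
            res = optimal_k(stats.zscore_table(table))
            hits += res["chosen_k"] == 2
        assert hits >= 18

    def test_single_blob_flagged_low_confidence(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        res = optimal_k(standardized(df, "abcd"), columns=list("abcd"))
        assert res["low_confidence"]


class TestLDA:
    def test_separable_groups_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "CA": np.concatenate([rng.normal(0, 0.1, 30), rng.normal(10, 0.1, 30)]),
            "DEN": np.concatenate([rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)]),
            "CC": rng.normal(size=60),
        })
        ident = np.array(["x"] * 30 + ["y"] * 30)
        model = lda_train_test(df, ident, seed=0)
        assert model.accuracy == 1.0
        assert model.n_axes == 1

    def test_four_groups_three_axes_df_nine(self, table1_table):
        z = stats.zscore_table(table1_table)
        cut = cut_and_identify(hca_ward_manhattan(z), 4, table1_table["roi"].to_numpy())
        keep = np.setdiff1d(np.arange(len(table1_table)), cut.minority_cells)
        ident = np.array([cut.identity[c] for c in cut.labels[keep]])
        model = lda_train_test(
            table1_table.iloc[keep].reset_index(drop=True), ident, seed=0
        )
        assert model.n_axes == 3
        assert model.proportion_of_trace.sum() == pytest.approx(1.0)
        lam, chi2, df, p = wilks_test(model)
        assert df == 9
        assert 0 < lam < 1 and chi2 > 0 and p < 1e-6

    def test_synthetic_accuracy_beats_chance(self):
        accs = []
        for seed in range(20):
            table = synthetic.generate_feature_table(
                synthetic.GROUP_SPECS_TABLE1, seed=100 + seed
            )
            z = stats.zscore_table(table)
            cut = cut_and_identify(hca_ward_manhattan(z), 4, table["roi"].to_numpy())
            keep = np.setdiff1d(np.arange(len(table)), cut.minority_cells)
            ident = np.array([cut.identity[c] for c in cut.labels[keep]])
            model = lda_train_test(
                table.iloc[keep].reset_index(drop=True), ident, seed=seed
            )
            accs.append(model.accuracy)
        assert np.mean(accs) >= 0.60  # far above the 0.25 chance level

    def test_predictor_order_does_not_change_predictions(self, table1_table):
        ident = table1_table["roi"].to_numpy()
        m1 = lda_train_test(table1_table, ident, predictors=("CA", "DEN", "CC"), seed=3)
        m2 = lda_train_test(table1_table, ident, predictors=("CC", "CA", "DEN"), seed=3)
        assert m1.accuracy == m2.accuracy
        assert (m1.predictions["predicted"] == m2.predictions["predicted"]).all()


class TestWilksClosedForm:
    def test_two_group_one_feature_equals_t_statistic_identity(self):
        # Lambda = 1 / (1 + t^2 / df) with the pooled two-sample t
        rng = np.random.default_rng(5)
        df_ = pd.DataFrame({
            "CA": np.concatenate([rng.normal(0, 1, 20), rng.normal(1.2, 1, 20)]),
            "DEN": rng.normal(size=40),
            "CC": rng.normal(size=40),
        })
        ident = np.array(["x"] * 20 + ["y"] * 20)
        model = lda_train_test(df_, ident, predictors=("CA",), train_frac=0.9, seed=0)
        lam, chi2, dfree, p = wilks_test(model)
        x = model._train_X[:, 0]
        y = model._train_y
        a, b = x[y == "x"], x[y == "y"]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert lam == pytest.approx(1.0 / (1.0 + t**2 / (na + nb - 2)), abs=1e-9)

    def test_identical_group_means_lambda_near_one(self):
        rng = np.random.default_rng(6)
        df_ = pd.DataFrame({
            "CA": rng.normal(size=60), "DEN": rng.normal(size=60),
            "CC": rng.normal(size=60),
        })
        ident = np.repeat(["x", "y"], 30)
        model = lda_train_test(df_, ident, seed=0)
        lam, chi2, dfree, p = wilks_test(model)
        assert lam > 0.8
        assert p > 0.01


class TestPCAPermutation:
    def test_single_latent_factor_only_pc1(self):
        rng = np.random.default_rng(7)
        n = 150
        f = rng.normal(size=n)
        cols = {f"v{j}": f + rng.normal(0, 0.05, n) for j in range(13)}
        df = pd.DataFrame(cols)
        res = pca_permutation(df, list(cols), n_permutations=199, n_bootstrap=199, seed=0)
        assert res.significant_pcs == [1]
        assert res.percent_ci[0, 1] <= 100.0
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_type_one_error_calibrated(self):
        hits = 0
        runs = 200
        for i in range(runs):
            rng = np.random.default_rng(i)
            df = pd.DataFrame(rng.normal(size=(50, 8)),
                              columns=[f"v{j}" for j in range(8)])
            res = pca_permutation(df, list(df.columns), n_permutations=99,
                                  n_bootstrap=0, seed=5000 + i)
            hits += 1 in res.significant_pcs
        assert 0.01 <= hits / runs <= 0.10

    def test_two_planted_factors_detected(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            n = 120
            f1, f2 = rng.normal(size=n), rng.normal(size=n)
            cols = {}
            for j in range(6):
                cols[f"a{j}"] = f1 + 0.35 * rng.normal(size=n)
            for j in range(4):
                cols[f"b{j}"] = 0.8 * f2 + 0.35 * rng.normal(size=n)
            for j in range(3):
                cols[f"c{j}"] = rng.normal(size=n)
            df = pd.DataFrame(cols)
            res = pca_permutation(df, list(cols), n_permutations=199,
                                  n_bootstrap=0, seed=i)
            hits += res.significant_pcs[:2] == [1, 2] and 3 not in res.significant_pcs
        assert hits >= 18

    def test_bootstrap_does_not_move_point_estimates(self, table1_table):
        params = list(PCA_PARAMETERS)
        a = pca_permutation(table1_table, params, n_permutations=99,
                            n_bootstrap=0, seed=1)
        b = pca_permutation(table1_table, params, n_permutations=99,
                            n_bootstrap=50, seed=1)
        np.testing.assert_allclose(a.percent_variance, b.percent_variance)

    def test_deterministic_given_seed(self, table1_table):
        params = list(PCA_PARAMETERS)
        a = pca_permutation(table1_table, params, n_permutations=99,
                            n_bootstrap=99, seed=2)
        b = pca_permutation(table1_table, params, n_permutations=99,
                            n_bootstrap=99, seed=2)
        assert np.array_equal(a.percent_ci, b.percent_ci)
        assert a.significant_pcs == b.significant_pcs


class TestNewickExport:
    def test_roundtrip_leaf_names_and_parse(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(6, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        tree = hca_ward_manhattan(df, columns=["a", "b", "c"])
        names = [f"leaf{i}" for i in range(6)]
        nwk = linkage_to_newick(tree.linkage, names)
        assert nwk.endswith(";")
        for n in names:
            assert n in nwk
        import dendropy

        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(parsed.leaf_nodes()) == 6
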