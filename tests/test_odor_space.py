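"""Distances, Ward clustering, PCA, ANOSIM, matrix correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import olfmap as om
from olfmap.odor_space import (DistanceMatrix, anosim, cut_dendrogram,
                               cut_dendrogram_k, cluster_signature_glomeruli,
                               hierarchical_cluster, matrix_correlation,
                               odor_distance_matrix, pca)

from conftest import make_matrix


class TestDistanceMatrix:
    def test_identical_vectors_zero_distance(self):
        m = make_matrix(np.tile([[3.0], [4.0]], (1, 4)))
        for metric in ("cosine", "euclidean"):
            d = odor_distance_matrix(m, metric)
            assert np.allclose(d.values, 0.0, atol=1e-12)

    def test_orthogonal_nonnegative_cosine_is_one(self):
        m = make_matrix(np.array([[1.0, 0.0], [0.0, 2.0]]))
        d = odor_distance_matrix(m, "cosine")
        assert d.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["cosine", "euclidean", "correlation"])
    def test_matches_bruteforce_pairwise_loop(self, metric, rng):
        vals = rng.normal(10, 15, (9, 7))
        m = make_matrix(vals)
        d = odor_distance_matrix(m, metric)
        for i in range(7):
            for j in range(7):
                u, v = vals[:, i], vals[:, j]
                if metric == "cosine":
                    exp = 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                elif metric == "euclidean":
                    exp = np.linalg.norm(u - v)
                else:
                    exp = 1 - np.corrcoef(u, v)[0, 1]
                assert d.values[i, j] == pytest.approx(exp, abs=1e-10)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_zero_norm_vector_distance_defined_as_one(self):
        m = make_matrix(np.array([[0.0, 1.0], [0.0, 2.0]]))
        d = odor_distance_matrix(m, "cosine")
        assert d.values[0, 1] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            odor_distance_matrix(make_matrix(np.ones((3, 1))), "cosine")


class TestHierarchicalCluster:
    def test_two_items_merge_at_their_distance(self):
        # Lance–Williams for a pair of singletons reduces to the input distance
        d = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 0.37], [0.37, 0]]),
                           metric="cosine")
        dend = hierarchical_cluster(d)
        assert dend.linkage[0, 2] == pytest.approx(0.37)

    def test_matches_lance_williams_oracle(self, rng):
        """Explicit Ward Lance–Williams recursion vs the linkage heights."""
        n = 6
        pts = rng.normal(0, 1, (n, 3))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dend = hierarchical_cluster(DistanceMatrix(
            labels=list("abcdef"), values=dm, metric="euclidean"))

        active = {i: ([i], dm) for i in range(n)}
        sizes = {i: 1 for i in range(n)}
        d2 = dm**2
        cur = {i: i for i in range(n)}
        dd = {(i, j): d2[i, j] for i in range(n) for j in range(n) if i < j}
        next_id = n
        heights = []
        members = {i: 1 for i in range(n)}
        while len(members) > 1:
            (i, j), dij2 = min(dd.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dij2))
            ni, nj = members.pop(i), members.pop(j)
            new = next_id
            next_id += 1
            updates = {}
            for k in list(members):
                nk = members[k]
                dik2 = dd.pop((min(i, k), max(i, k)))
                djk2 = dd.pop((min(j, k), max(j, k)))
                updates[(k, new)] = ((ni + nk) * dik2 + (nj + nk) * djk2
                                     - nk * dij2) / (ni + nj + nk)
            dd = {kv: v for kv, v in dd.items() if i not in kv and j not in kv}
            for (k, m), v in updates.items():
                dd[(min(k, m), max(k, m))] = v
            members[new] = ni + nj
        assert dend.linkage[:, 2] == pytest.approx(np.sort(heights), abs=1e-9)

    def test_planted_groups_recovered(self):
        panel = om.generate_panel(8, 9, seed=1)
        model = om.generate_model(panel, n_classes=31, n_groups=3,
                                  within_group_gain=10.0, seed=1)
        d = odor_distance_matrix(model.mean_rate, "cosine")
        labels = cut_dendrogram_k(hierarchical_cluster(d), 3)
        planted = [model.group_of_odor[o] for o in labels.index]
        assert adjusted_rand_score(planted, labels.to_numpy()) >= 0.9


class TestCutDendrogram:
    @pytest.fixture()
    def dend(self, rng):
        vals = rng.uniform(0, 50, (10, 8))
        return hierarchical_cluster(odor_distance_matrix(make_matrix(vals), "cosine"))

    def test_cut_above_root_one_cluster(self, dend):
        assert cut_dendrogram(dend, dend.max_height * 1.01).nunique() == 1

    def test_cut_below_all_merges_singletons(self, dend):
        assert cut_dendrogram(dend, 1e-9).nunique() == 8

    def test_cluster_count_monotone_in_threshold(self, dend):
        counts = [cut_dendrogram(dend, t).nunique()
                  for t in np.linspace(1e-6, dend.max_height * 1.1, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_fraction_of_max_mode(self, dend):
        abs_cut = cut_dendrogram(dend, 0.7 * dend.max_height, "absolute")
        frac_cut = cut_dendrogram(dend, 0.7, "fraction_of_max")
        assert (abs_cut == frac_cut).all()


class TestSignatureGlomeruli:
    def test_all_zero_matrix_empty_sets(self):
        m = make_matrix(np.zeros((3, 4)))
        clusters = pd.Series([1, 1, 2, 2], index=m.odor_ids)
        sigs = cluster_signature_glomeruli(m, clusters, 30.0)
        assert all(len(s) == 0 for s in sigs.values())

    def test_zero_threshold_includes_everything(self, rng):
        m = make_matrix(rng.uniform(1, 9, (3, 4)))
        clusters = pd.Series([1, 1, 2, 2], index=m.odor_ids)
        sigs = cluster_signature_glomeruli(m, clusters, 0.0)
        assert all(s == set(m.class_ids) for s in sigs.values())

    def test_mean_over_cluster_odors(self):
        vals = np.array([[60.0, 0.0, 10.0], [10.0, 20.0, 90.0]])
        m = make_matrix(vals, glomeruli=["GA", "GB"])
        clusters = pd.Series([1, 1, 2], index=m.odor_ids)
        sigs = cluster_signature_glomeruli(m, clusters, 30.0)
        assert sigs[1] == {"GA"}   # mean(60, 0) = 30 ≥ 30; GB mean 15 < 30
        assert sigs[2] == {"GB"}


class TestPca:
    def test_rank_one_input(self):
        u = np.outer([1.0, 2.0, 3.0], [1.0, 0.5, 2.0, 1.5])
        res = pca(make_matrix(u), items="odors")
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_two_route_eigendecomposition_oracle(self, rng):
        vals = rng.normal(0, 5, (9, 12))
        res = pca(make_matrix(vals), items="odors")
        x = vals.T - vals.T.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1][: len(res.explained_variance_fraction)]
        assert res.explained_variance_fraction == pytest.approx(
            evals / np.linalg.eigvalsh(np.cov(x.T)).sum(), abs=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA
        vals = rng.normal(0, 5, (7, 10))
        res = pca(make_matrix(vals), items="odors")
        sk = SkPCA().fit(vals.T)
        assert res.explained_variance_fraction[:5] == pytest.approx(
            sk.explained_variance_ratio_[:5], abs=1e-9)

    def test_centering_invariance_to_column_offsets(self, rng):
        vals = rng.normal(0, 5, (6, 8))
        shifted = vals + rng.normal(0, 50, (6, 1))  # constant per class
        f1 = pca(make_matrix(vals), items="odors").explained_variance_fraction
        f2 = pca(make_matrix(shifted), items="odors").explained_variance_fraction
        assert f1 == pytest.approx(f2, abs=1e-9)


class TestAnosim:
    def test_perfect_separation_r_is_one(self, rng):
        x = np.zeros((3, 8))
        x[:, :4] = rng.uniform(0, 1, (3, 4))
        x[:, 4:] = 10 + rng.uniform(0, 1, (3, 4))
        r, p = anosim(make_matrix(x), ["a"] * 4 + ["b"] * 4, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_skbio_oracle(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim
        d = np.abs(rng.normal(0, 1, (12, 12)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [str(i) for i in range(12)]
        labels = ["g1"] * 6 + ["g2"] * 6
        ours_r, _ = anosim(DistanceMatrix(labels=ids, values=d, metric="euclidean"),
                           labels, n_perm=99, seed=0)
        res = sk_anosim(SkDM(d, ids), labels, permutations=99)
        assert ours_r == pytest.approx(res["test statistic"], abs=1e-12)

    def test_r_bounded_and_rank_invariant(self, rng):
        d = squareform(rng.uniform(0.1, 5.0, 45))
        dm = DistanceMatrix(labels=[str(i) for i in range(10)], values=d,
                            metric="euclidean")
        labels = ["a"] * 5 + ["b"] * 5
        r1, _ = anosim(dm, labels, n_perm=49, seed=3)
        # monotone transform of distances leaves the rank-based R unchanged
        dm2 = DistanceMatrix(labels=dm.labels, values=np.sqrt(d), metric="euclidean")
        r2, _ = anosim(dm2, labels, n_perm=49, seed=3)
        assert -1 <= r1 <= 1
        assert r1 == pytest.approx(r2)

    def test_group_of_one_rejected(self, rng):
        m = make_matrix(rng.uniform(0, 9, (3, 5)))
        with pytest.raises(ValueError, match="≥2 members"):
            anosim(m, ["a", "a", "a", "a", "b"], n_perm=9)

    def test_valence_separation_on_planted_data(self, small_model, small_panel):
        r, p = anosim(small_model.mean_rate,
                      [small_panel.valence[o] for o in small_model.mean_rate.columns],
                      n_perm=999, seed=5)
        assert p < 0.05


class TestMatrixCorrelation:
    def _random_dm(self, rng, n=10):
        d = squareform(rng.uniform(0.1, 5.0, n * (n - 1) // 2))
        return DistanceMatrix(labels=[f"i{k}" for k in range(n)], values=d,
                              metric="euclidean")

    def test_self_correlation_is_one(self, rng):
        d = self._random_dm(rng)
        r, p, _ = matrix_correlation(d, d)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_label_shuffle_control_near_zero(self, rng):
        d = self._random_dm(rng, n=12)
        r, p, (smean, ssd) = matrix_correlation(d, d, shuffle=(200, 7))
        assert abs(smean) < 3 * ssd / np.sqrt(200) + 0.02

    def test_independent_matrices_uncorrelated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r, p, _ = matrix_correlation(self._random_dm(rng), self._random_dm(rng))
            hits += p > 0.05
        assert hits >= 18  # ≥90% of independent pairs non-significant

    def test_mismatched_labels_rejected(self, rng):
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix(labels=[f"x{k}" for k in range(10)],
                            values=d1.values, metric="euclidean")
        with pytest.raises(ValueError, match="label"):
            matrix_correlation(d1, d2)
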