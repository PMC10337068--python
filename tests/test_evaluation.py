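from itertools import permutations

import numpy as np
import pytest

import kpcaig as kg
from kpcaig.ranking import FeatureRanking


def labels_from_contingency(C):
    """Expand a contingency table into (true, pred) label vectors."""
    t, p = [], []
    for i, row in enumerate(C):
        for j, count in enumerate(row):
            t += [i] * count
            p += [j] * count
    return np.array(t), np.array(p)


def exhaustive_accuracy(C):
    """Brute-force best one-to-one matching over all permutations."""
    C = np.asarray(C)
    k = max(C.shape)
    M = np.zeros((k, k), dtype=int)
    M[: C.shape[0], : C.shape[1]] = C
    best = max(sum(M[i, pi] for i, pi in enumerate(perm))
               for perm in permutations(range(k)))
    return best / C.sum()


def oracle_and_reversed(ds):
    """Ground-truth ranking (informative first) and its reversal."""
    rest = np.setdiff1d(np.arange(ds.p), ds.informative)
    order = np.concatenate([ds.informative, rest])
    zeros = np.zeros(ds.p)
    ids = list(ds.X.columns)
    return (FeatureRanking(ids, zeros, zeros, order),
            FeatureRanking(ids, zeros, zeros, order[::-1]))


class TestClusteringAccuracy:
    def test_identical_labelings(self):
        y = np.array([0, 0, 1, 1, 2])
        assert kg.clustering_accuracy(y, y) == 1.0

    def test_relabeling_invariance(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        relabeled = np.array([2, 2, 0, 0, 1, 1])
        assert kg.clustering_accuracy(y, relabeled) == 1.0

    def test_contingency_example(self):
        t, p = labels_from_contingency([[5, 1], [2, 4]])
        assert kg.clustering_accuracy(t, p) == pytest.approx(0.75)

    def test_matches_exhaustive_assignment(self):
        """Hungarian matcher agrees with brute-force enumeration on random
        contingency tables with up to 5 clusters."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            k1, k2 = rng.integers(2, 6, size=2)
            C = rng.integers(0, 8, size=(k1, k2))
            if C.sum() == 0:
                continue
            t, p = labels_from_contingency(C)
            assert kg.clustering_accuracy(t, p) == pytest.approx(
                exhaustive_accuracy(C))

    def test_beats_greedy_matching(self):
        # greedy (largest-first) picks (0,0)=6 then (1,1)=1 -> 7/18;
        # optimal picks (0,1)+(1,0)=5+6=11/18
        C = [[6, 5], [6, 1]]
        t, p = labels_from_contingency(C)
        assert kg.clustering_accuracy(t, p) == pytest.approx(11 / 18)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kg.clustering_accuracy([0, 1], [0, 1, 1])


class TestNMI:
    def test_identical_labelings(self):
        y = [0, 0, 1, 1, 2]
        assert kg.normalized_mutual_information(y, y) == pytest.approx(1.0)

    def test_single_cluster_degenerate_case(self):
        assert kg.normalized_mutual_information([0, 0, 0], [1, 1, 1]) == 1.0

    def test_constant_prediction_is_zero(self):
        assert kg.normalized_mutual_information([0, 0, 1, 1], [5, 5, 5, 5]) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 4, size=40)
        assert kg.normalized_mutual_information(a, b) == pytest.approx(
            kg.normalized_mutual_information(b, a))

    def test_entropy_arithmetic_oracle(self):
        """Geometric-mean NMI of contingency [[5,1],[2,4]] recomputed from
        first principles (plug-in entropies, 0 log 0 = 0)."""
        C = np.array([[5, 1], [2, 4]], dtype=float)
        n = C.sum()
        pt, pp = C.sum(1) / n, C.sum(0) / n
        ht = -np.sum(pt * np.log(pt))
        hp = -np.sum(pp * np.log(pp))
        pij = C / n
        mi = sum(pij[i, j] * np.log(pij[i, j] / (pt[i] * pp[j]))
                 for i in range(2) for j in range(2) if pij[i, j] > 0)
        expect = mi / np.sqrt(ht * hp)
        t, p = labels_from_contingency([[5, 1], [2, 4]])
        assert kg.normalized_mutual_information(t, p) == pytest.approx(expect)

    def test_arithmetic_variant_available(self):
        t, p = labels_from_contingency([[5, 1], [2, 4]])
        geo = kg.normalized_mutual_information(t, p)
        ari = kg.normalized_mutual_information(t, p, average="arithmetic")
        assert 0 < ari <= 1 and 0 < geo <= 1

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 4, size=30)
            v = kg.normalized_mutual_information(a, b)
            assert 0.0 <= v <= 1.0


class TestSubsetKmeansEval:
    def test_separable_fixture_reaches_full_accuracy(self, separable):
        oracle, _ = oracle_and_reversed(separable)
        report = kg.subset_kmeans_eval(separable.X, separable.labels, oracle,
                                       [10], k=3, runs=5, seed=0)
        assert report.loc[0, "acc_mean"] == pytest.approx(1.0)
        assert report.loc[0, "nmi_mean"] == pytest.approx(1.0)

    def test_fixed_seed_is_reproducible(self, separable):
        oracle, _ = oracle_and_reversed(separable)
        r1 = kg.subset_kmeans_eval(separable.X, separable.labels, oracle,
                                   [10, 30], k=3, runs=1, seed=3)
        r2 = kg.subset_kmeans_eval(separable.X, separable.labels, oracle,
                                   [10, 30], k=3, runs=1, seed=3)
        assert r1.equals(r2)

    def test_oracle_dominates_reversed_ranking(self, separable):
        oracle, reverse = oracle_and_reversed(separable)
        d_grid = [10, 40, 70, 100]  # up to p/2
        ro = kg.subset_kmeans_eval(separable.X, separable.labels, oracle,
                                   d_grid, k=3, runs=5, seed=7)
        rr = kg.subset_kmeans_eval(separable.X, separable.labels, reverse,
                                   d_grid, k=3, runs=5, seed=7)
        assert np.all(ro["acc_mean"].to_numpy() > rr["acc_mean"].to_numpy())

    def test_parameter_validation(self, separable):
        oracle, _ = oracle_and_reversed(separable)
        with pytest.raises(ValueError):
            kg.subset_kmeans_eval(separable.X, separable.labels, oracle, [10],
                                  k=1)
        with pytest.raises(ValueError):
            kg.subset_kmeans_eval(separable.X, separable.labels, oracle, [10],
                                  k=separable.n + 1)
        with pytest.raises(ValueError):
            kg.subset_kmeans_eval(separable.X, separable.labels, oracle,
                                  [separable.p + 1], k=3)


class TestSilhouetteCurve:
    def test_separated_clusters_score_high(self):
        ds = kg.make_clustered_data(n=40, p=30, n_informative=10, n_clusters=2,
                                    separation=6.0, noise_sd=1.0, seed=3)
        oracle, _ = oracle_and_reversed(ds)
        curve = kg.silhouette_curve(ds.X, oracle, [10], n_clusters=2, q=2,
                                    seed=0)
        assert curve.loc[0, "silhouette"] > 0.8

    def test_noise_scores_stay_at_null_floor(self):
        """Unstructured data cannot exceed the forced-bisection floor: k-means
        always splits the 2-D embedding of a single Gaussian cloud, which
        carries a silhouette around 0.3-0.4, far below the separated-cluster
        regime (>0.8)."""
        ds = kg.make_clustered_data(n=40, p=60, n_informative=0, n_clusters=2,
                                    separation=0.0, seed=8)
        rk = kg.make_random_ranking(60, seed=0, feature_ids=list(ds.X.columns))
        curve = kg.silhouette_curve(ds.X, rk, [30], n_clusters=2, q=2, seed=0)
        assert abs(curve.loc[0, "silhouette"]) < 0.5

    def test_informative_ranking_beats_random(self, separable):
        sigma = kg.select_sigma(separable.X, q=3)
        model = kg.fit(separable.X, kg.KernelSpec("rbf", sigma), q=3)
        ranking = kg.rank_features(model)
        curve = kg.silhouette_curve(separable.X, ranking, [10, 30], n_clusters=3,
                                    q=3, random_rankings=3, seed=5)
        piv = curve.pivot(index="d", columns="ranking", values="silhouette")
        rand_cols = [c for c in piv.columns if c.startswith("random")]
        assert np.all(piv["kpca-ig"].to_numpy()[:, None]
                      >= piv[rand_cols].to_numpy())

    def test_small_subsets_skipped_with_warning(self, separable):
        oracle, _ = oracle_and_reversed(separable)
        with pytest.warns(UserWarning, match="skipped"):
            curve = kg.silhouette_curve(separable.X, oracle, [2, 10],
                                        n_clusters=3, q=2, seed=0)
        assert curve["d"].tolist() == [10]


class TestTrainTestVarianceCurve:
    def test_columns_and_determinism(self, separable):
        curve = kg.train_test_variance_curve(separable.X, [10, 50], q=2,
                                             splits=2, seed=4)
        again = kg.train_test_variance_curve(separable.X, [10, 50], q=2,
                                             splits=2, seed=4)
        assert curve.equals(again)
        assert {"split", "d", "train_ev", "test_ev"} <= set(curve.columns)
        assert ((curve["train_ev"] > 0) & (curve["train_ev"] <= 1)).all()

    def test_full_subset_uses_all_features(self, separable):
        curve = kg.train_test_variance_curve(separable.X, [separable.p], q=2,
                                             splits=1, sigma_strategy=1e-4,
                                             seed=0)
        # direct refit on the same split must reproduce the recorded values
        rng = np.random.default_rng(np.random.SeedSequence(0).spawn(1)[0])
        perm = rng.permutation(separable.n)
        n_train = int(round(0.75 * separable.n))
        m = kg.fit(separable.X.iloc[perm[:n_train]], kg.KernelSpec("rbf", 1e-4),
                   q=2)
        assert curve.loc[0, "train_ev"] == pytest.approx(
            float(kg.explained_variance(m).sum()))

    def test_invalid_fraction(self, separable):
        with pytest.raises(ValueError):
            kg.train_test_variance_curve(separable.X, [10], train_fraction=1.2)
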