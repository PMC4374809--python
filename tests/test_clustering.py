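"""Shape clustering, ratio curves and spreading calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pirnaspread import clustering
from pirnaspread.clustering import (LOSS_3PRIME, LOSS_5PRIME, NONE,
                                    RatioCurve, SpreadingKMeans,
                                    call_spreading, kmeans, ratio_curves,
                                    select_k, to_proportions)


def two_clouds(rng, n_per=6, sep=10.0):
    a = rng.normal(0.0, 0.3, size=(n_per, 10))
    b = rng.normal(sep, 0.3, size=(n_per, 10))
    return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)


class TestKMeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        res = kmeans(X, 1, seed=0)
        assert np.allclose(res.centroids[0], X.mean(axis=0))

    def test_separated_clouds_match_brute_force_partition(self):
        rng = np.random.default_rng(1)
        X, labels = two_clouds(rng, n_per=6, sep=10.0)
        res = kmeans(X, 2, seed=0)

        # brute-force optimal 2-partition over all 2^12 assignments
        best, best_obj = None, np.inf
        for assign in itertools.product([0, 1], repeat=len(X)):
            assign = np.array(assign)
            if assign.min() == assign.max():
                continue
            obj = sum(((X[assign == c] - X[assign == c].mean(0)) ** 2).sum()
                      for c in (0, 1))
            if obj < best_obj:
                best, best_obj = assign, obj
        got = np.array([res.assignments[str(i)] for i in range(len(X))])
        assert (got == best).all() or (got == 1 - best).all()
        assert res.inertia == pytest.approx(best_obj, rel=1e-9)

    def test_same_seed_identical_result(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10))
        r1 = kmeans(X, 4, seed=9)
        r2 = kmeans(X, 4, seed=9)
        assert r1.assignments == r2.assignments
        assert np.array_equal(r1.centroids, r2.centroids)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        res = kmeans(X, 5, seed=1, n_init=1)
        hist = np.array(res.objective_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_matches_sklearn_objective(self):
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(i * 3, 0.4, size=(20, 10)) for i in range(4)])
        ours = kmeans(X, 4, seed=0)
        sk = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)

    def test_invalid_k_rejected(self):
        X = np.zeros((5, 10)) + np.arange(5)[:, None]
        with pytest.raises(ValueError):
            kmeans(X, 0)
        with pytest.raises(ValueError):
            kmeans(X, 6)

    def test_too_few_distinct_rows_rejected(self):
        X = np.ones((10, 10))
        with pytest.raises(ValueError, match="distinct"):
            kmeans(X, 2)


class TestSelectK:
    def test_largest_converged_k_wins(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(i * 4, 0.3, size=(15, 10)) for i in range(5)])
        k, report, results = select_k(X, k_range=range(2, 6), seed=0)
        assert report.converged.all()
        assert k == 5
        assert set(results) == {2, 3, 4, 5}

    def test_single_k_range(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        k, report, _ = select_k(X, k_range=[3], seed=0)
        assert k == 3 and len(report) == 1


class TestProportions:
    def test_rows_sum_to_one(self):
        df = pd.DataFrame(np.random.default_rng(7).poisson(5, size=(8, 10)) + 1.0,
                          index=[f"g{i}" for i in range(8)])
        props = to_proportions(df)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_zero_rows_rejected(self):
        df = pd.DataFrame(np.zeros((2, 10)), index=["a", "b"])
        with pytest.raises(ValueError, match="zero-total"):
            to_proportions(df)

    def test_filter_targeted_threshold(self):
        df = pd.DataFrame([[0.0] * 10, [1.0] + [0.0] * 9], index=["z", "g"])
        kept = clustering.filter_targeted(df, min_reads=1.0)
        assert list(kept.index) == ["g"]


def _result_for(genes, labels):
    return clustering.ClusterResult(
        k=len(set(labels)), assignments=dict(zip(genes, labels)),
        centroids=np.zeros((len(set(labels)), 10)), seed=0, converged=True,
        n_iter=1, inertia=0.0)


class TestRatioCurves:
    def test_identical_conditions_all_zero(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(12)]
        bins = pd.DataFrame(rng.poisson(20, size=(12, 10)).astype(float),
                            index=genes)
        res = _result_for(genes, [0] * 6 + [1] * 6)
        curves = ratio_curves(res, bins, bins, (1000.0, 1000.0))
        for c in curves:
            assert np.allclose(c.values, 0.0)

    def test_library_size_scaling_cancels(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(10)]
        wt = pd.DataFrame(rng.poisson(30, size=(10, 10)).astype(float),
                          index=genes)
        mut = wt * 2.0
        res = _result_for(genes, [0] * 10)
        curves = ratio_curves(res, mut, wt, (2000.0, 1000.0))
        assert np.allclose(curves[0].values, 0.0)

    def test_five_prime_loss_shape(self):
        genes = [f"g{i}" for i in range(6)]
        wt = pd.DataFrame(np.full((6, 10), 100.0), index=genes)
        mut = wt.copy()
        mut.iloc[:, :5] = 0.0
        res = _result_for(genes, [0] * 6)
        (curve,) = ratio_curves(res, mut, wt, (1000.0, 1000.0))
        assert (curve.values[:5] < -3).all()
        assert np.allclose(curve.values[5:], 0.0)

    def test_missing_gene_rejected(self):
        res = _result_for(["a", "b"], [0, 0])
        bins = pd.DataFrame(np.ones((1, 10)), index=["a"])
        with pytest.raises(ValueError, match="missing"):
            ratio_curves(res, bins, bins, (1.0, 1.0))


class TestCallSpreading:
    def test_flat_curve_none(self):
        calls = call_spreading([RatioCurve(0, np.zeros(10), 5)])
        assert calls[0].label == NONE and calls[0].index == 0.0

    def test_five_prime_loss_called(self):
        vals = np.array([-2.0] * 5 + [0.0] * 5)
        (call,) = call_spreading([RatioCurve(0, vals, 5)])
        assert call.index == pytest.approx(-2.0)
        assert call.label == LOSS_5PRIME

    def test_antisymmetric_under_reversal(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=10)
        (fwd,) = call_spreading([RatioCurve(0, vals, 5)], threshold=0.1)
        (rev,) = call_spreading([RatioCurve(0, vals[::-1].copy(), 5)],
                                threshold=0.1)
        assert fwd.index == pytest.approx(-rev.index)
        flip = {LOSS_5PRIME: LOSS_3PRIME, LOSS_3PRIME: LOSS_5PRIME, NONE: NONE}
        assert rev.label == flip[fwd.label]

    def test_non_finite_curve_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            call_spreading([RatioCurve(0, np.array([np.nan] * 10), 5)])


class TestSpreadingKMeans:
    def test_sklearn_style_fit_attributes(self):
        rng = np.random.default_rng(11)
        X, labels = two_clouds(rng, n_per=10, sep=8.0)
        X = np.abs(X) + 0.1
        est = SpreadingKMeans(n_clusters=2, random_state=0)
        est.fit(X)
        for attr in ("cluster_centers_", "labels_", "inertia_", "n_iter_",
                     "converged_"):
            assert hasattr(est, attr)
        assert len(est.labels_) == len(X)
        assert est.predict(X).tolist() == est.labels_.tolist()

    def test_get_set_params_roundtrip(self):
        est = SpreadingKMeans(n_clusters=3)
        params = est.get_params()
        assert params["n_clusters"] == 3
        est.set_params(n_clusters=5, random_state=7)
        assert est.n_clusters == 5 and est.random_state == 7
        with pytest.raises(ValueError, match="[Ii]nvalid|unknown"):
            est.set_params(bogus=1)

    def test_clone_compatible(self):
        from sklearn.base import clone
        est = clone(SpreadingKMeans(n_clusters=4, random_state=3))
        assert est.n_clusters == 4 and est.random_state == 3

    def test_proportion_scaling_makes_shape_clusters(self):
        # same shape at different abundance must cluster together
        rng = np.random.default_rng(12)
        shape_a = np.array([5, 4, 3, 2, 1, 1, 1, 1, 1, 1], float)
        shape_b = shape_a[::-1].copy()
        rows, truth = [], []
        for i in range(20):
            scale = rng.uniform(1, 100)
            base = shape_a if i % 2 == 0 else shape_b
            rows.append(base * scale + rng.uniform(0, 0.1, 10))
            truth.append(i % 2)
        est = SpreadingKMeans(n_clusters=2, random_state=0).fit(np.array(rows))
        truth = np.array(truth)
        assert (est.labels_ == truth).all() or (est.labels_ == 1 - truth).all()

    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError, match="fit"):
            SpreadingKMeans().predict(np.ones((2, 10)))
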