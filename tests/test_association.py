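"""Distance correlation, kNN machinery and the significance procedure."""

import numpy as np
import pandas as pd
import pytest

from repairkinetics import (
    KJMAParams,
    binarize,
    distance_correlation,
    knn_predict,
    prediction_error,
    repair_rate,
    significance_test,
    feature_association_test,
    trim_percentile,
    xr_model_correlation,
    zscore,
)
from repairkinetics.simulate import random_region_specs, ground_truth_frame


def brute_force_dcor(u, v):
    """Textbook O(n^2) distance correlation with explicit loops."""
    n = len(u)
    a = [[abs(u[i] - u[j]) for j in range(n)] for i in range(n)]
    b = [[abs(v[i] - v[j]) for j in range(n)] for i in range(n)]

    def center(d):
        row = [sum(r) / n for r in d]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)]
                for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvar_u = sum(x * x for r in A for x in r) / n**2
    dvar_v = sum(x * x for r in B for x in r) / n**2
    if dvar_u == 0 or dvar_v == 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvar_u * dvar_v) ** 0.5) ** 0.5


class TestDistanceCorrelation:
    def test_exact_linear_dependence(self, rng):
        u = rng.normal(size=20)
        assert distance_correlation(u, 3 * u + 1) == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_constant_vector_convention(self, rng):
        with pytest.warns(UserWarning):
            assert distance_correlation(np.full(10, 2.0),
                                        rng.normal(size=10)) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 51))
            u, v = rng.normal(size=n), rng.normal(size=n)
            assert distance_correlation(u, v) == pytest.approx(
                brute_force_dcor(list(u), list(v)), abs=1e-10)

    def test_symmetry_and_affine_invariance(self, rng):
        u, v = rng.normal(size=30), rng.normal(size=30)
        d = distance_correlation(u, v)
        assert distance_correlation(v, u) == pytest.approx(d, abs=1e-12)
        assert distance_correlation(2.5 * u - 7, v) == pytest.approx(d,
                                                                     abs=1e-10)

    def test_bounded(self, rng):
        for _ in range(10):
            u, v = rng.normal(size=15), rng.normal(size=15)
            assert 0.0 <= distance_correlation(u, v) <= 1.0


class TestTrim:
    def test_ranked_values_trimmed_to_95(self):
        mask = trim_percentile(np.arange(100, dtype=float))
        assert mask.sum() == 95 and not mask[-1]

    def test_disabled_retains_all(self):
        assert trim_percentile(np.arange(10.0), enabled=False).all()

    def test_all_equal_values_retained(self):
        assert trim_percentile(np.full(20, 3.0)).all()


class TestBinarize:
    def test_clean_split(self):
        assert binarize(np.array([1.0, 2.0, 3.0, 4.0])).tolist() == [0, 0, 1, 1]

    def test_balanced_for_any_input(self, rng):
        for n in (4, 7, 50, 101):
            c = binarize(rng.normal(size=n))
            assert abs(int((c == 0).sum()) - int((c == 1).sum())) <= 1

    def test_median_ties_split_across_classes(self):
        c = binarize(np.array([5.0, 5.0, 1.0, 9.0]))
        assert c[0] != c[1]           # the two 5s land in different classes
        assert c[2] == 0 and c[3] == 1

    def test_uninformative_feature_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.full(10, 1.0))


class TestZScore:
    def test_columns_standardised(self, rng):
        Z = zscore(rng.normal(5, 3, size=(40, 3)))
        assert np.abs(Z.mean(axis=0)).max() <= 1e-12
        assert Z.std(axis=0) == pytest.approx(np.ones(3), abs=1e-12)

    def test_affine_invariance_of_column(self, rng):
        X = rng.normal(size=(30, 1))
        assert zscore(4 * X + 11) == pytest.approx(zscore(X), abs=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones((10, 2)))


class TestKNN:
    def test_exact_match_k1(self):
        X = np.array([[0.0, 0], [1, 1], [2, 2]])
        c = np.array([1, 0, 1])
        assert knn_predict(X, c, [[1.0, 1.0]], 1)[0] == 0

    def test_hand_worked_majority(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        c = np.array([0, 0, 1, 1])
        assert knn_predict(X, c, [[0.0, 0.5]], 3)[0] == 0

    def test_k_equals_n_train_yields_global_majority(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        c = np.array([1, 1, 1, 0, 0])
        pred = knn_predict(X, c, [[100.0, 100.0], [-5.0, -5.0]], 5)
        assert pred.tolist() == [1, 1]

    def test_vote_tie_falls_back_to_nearest(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        c = np.array([0, 0, 1, 1])
        # query nearer the class-0 pair; k=4 vote is tied 2-2
        assert knn_predict(X, c, [[2.0]], 4)[0] == 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros((3, 2)), np.zeros(3), np.zeros((1, 2)), 4)

    def test_self_training_error_zero(self, rng):
        X = rng.normal(size=(25, 3))
        c = rng.integers(0, 2, size=25)
        pred = knn_predict(X, c, X, 1)
        assert prediction_error(pred, c) == 0.0


class TestPredictionError:
    def test_fraction(self):
        true = np.zeros(100, dtype=int)
        pred = true.copy()
        pred[:25] = 1
        assert prediction_error(pred, true) == 0.25
        assert prediction_error(true, true) == 0.0

    def test_random_balanced_labels_near_half(self, rng):
        a = rng.integers(0, 2, size=1000)
        b = rng.integers(0, 2, size=1000)
        assert prediction_error(a, b) == pytest.approx(0.5, abs=0.05)


def _params_frame(n, rng):
    gt = ground_truth_frame(random_region_specs(n, rng))
    return gt.reset_index()[["m", "beta", "theta"]]


class TestSignificance:
    def test_separable_feature_significant_for_all_ks(self, rng):
        df = _params_frame(250, rng)
        res = feature_association_test(
            df, df["m"].to_numpy(), feature="m-derived",
            ks=(5, 10, 20, 50, 100), n_repeats=30, seed=1,
        )
        assert res.significant and res.n_significant_k == 5

    def test_independent_labels_not_significant(self, rng):
        df = _params_frame(250, rng)
        res = feature_association_test(
            df, rng.normal(size=250), feature="null",
            ks=(5, 10, 20, 50, 100), n_repeats=30, seed=2,
        )
        assert not res.significant

    def test_identical_seed_identical_result(self, rng):
        df = _params_frame(120, rng)
        feat = rng.normal(size=120)
        r1 = feature_association_test(df, feat, ks=(5, 10), n_repeats=10,
                                      seed=9)
        r2 = feature_association_test(df, feat, ks=(5, 10), n_repeats=10,
                                      seed=9)
        for k in (5, 10):
            assert np.array_equal(r1.per_k[k]["true_errors"],
                                  r2.per_k[k]["true_errors"])
            assert r1.per_k[k]["p_value"] == r2.per_k[k]["p_value"]
        assert r1.significant == r2.significant

    def test_three_of_five_rule(self, rng):
        X = zscore(rng.normal(size=(60, 3)))
        c = binarize(rng.normal(size=60))
        res = significance_test(X, c, ks=(3, 5), n_repeats=5, seed=0)
        # with only two ks evaluated, the 3-of-5 default cannot be met
        assert res.n_significant_k <= 2 and not res.significant

    def test_misconfiguration_rejected(self, rng):
        X = zscore(rng.normal(size=(20, 3)))
        c = binarize(rng.normal(size=20))
        with pytest.raises(ValueError):
            significance_test(X, c, ks=(5,), n_repeats=1)
        with pytest.raises(ValueError):
            significance_test(X, c, ks=(50,), n_repeats=5)


class TestXRCorrelation:
    def _fits(self, rng, n=50):
        specs = random_region_specs(n, rng, prefix="g")
        return {
            s.region_id: KJMAParams(m=s.m, tau=s.tau, theta=s.theta)
            for s in specs
        }

    def test_self_consistent_xr_gives_dc_one(self, rng):
        fits = self._fits(rng)
        xr = {
            rid: {t: 7.0 * np.sqrt(repair_rate(p, t)) for t in (5.0, 20.0, 60.0)}
            for rid, p in fits.items()
        }
        res = xr_model_correlation(fits, xr)
        assert res["model_dc"] == pytest.approx(1.0, abs=1e-10)
        assert res["n_points"] == 150 and res["n_dropped"] == 0

    def test_independent_noise_gives_low_dc(self, rng):
        fits = self._fits(rng, n=67)  # 67 regions x 3 times ~ 200 points
        xr = {rid: {t: float(rng.normal()) for t in (5.0, 20.0, 60.0)}
              for rid in fits}
        res = xr_model_correlation(fits, xr)
        assert res["model_dc"] <= 0.2

    def test_regions_without_fits_are_dropped_and_counted(self, rng):
        fits = self._fits(rng, n=10)
        xr = {rid: {5.0: 1.0, 20.0: 2.0, 60.0: 1.5} for rid in fits}
        xr["orphan"] = {5.0: 3.0}
        res = xr_model_correlation(fits, xr)
        assert res["n_dropped"] == 1
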