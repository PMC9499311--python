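"""Linking fitted repair parameters to genomic features.

Two statistical tools live here.  Distance correlation (the biased
V-statistic via double-centered pairwise-distance matrices) measures possibly
non-linear dependence between the model's predicted repair rates and
independently probed excision-repair signal.  The kNN significance procedure
asks whether a feature (transcription rate, nucleosome density, TU length,
...) can be predicted from the fitted (m, beta, theta) triples better than
chance: the feature is trimmed and median-split into balanced high/low
classes, a k-nearest-neighbour classifier on z-scored parameters is compared
against the same classifier trained on shuffled labels over many random
train/test splits, and an association is declared when the true model beats
the shuffled one significantly for at least three of the evaluated k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .model import KJMAParams, RepairTimeCourse, repair_rate
from .signal import empirical_repair_rate

__all__ = [
    "AssociationResult",
    "distance_correlation",
    "xr_model_correlation",
    "trim_percentile",
    "binarize",
    "zscore",
    "knn_predict",
    "prediction_error",
    "significance_test",
    "feature_association_test",
    "DEFAULT_KS",
]

DEFAULT_KS = (5, 10, 20, 50, 100)


def distance_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Sample distance correlation in [0, 1] (biased V-statistic form).

    Pairwise absolute-difference matrices of each vector are double-centered;
    the distance covariance is the mean elementwise product, normalised by
    the geometric mean of the distance variances.  A constant vector has zero
    distance variance and yields 0 by convention (with a warning).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if len(u) != len(v) or len(u) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")

    def centered(x: np.ndarray) -> np.ndarray:
        d = np.abs(x[:, None] - x[None, :])
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    A, B = centered(u), centered(v)
    dvar_u = (A * A).mean()
    dvar_v = (B * B).mean()
    if dvar_u == 0.0 or dvar_v == 0.0:
        warnings.warn("constant input vector: distance correlation set to 0")
        return 0.0
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_u * dvar_v)))


def trim_percentile(
    values: np.ndarray, percentile: float = 95.0, enabled: bool = True
) -> np.ndarray:
    """Mask selecting values at or below the given percentile.

    Skewed features with heavy right tails are trimmed to their lower 95th
    percentile before analysis; approximately normal features (e.g. MNase-seq
    nucleosome density) pass through untouched (``enabled=False``).
    """
    values = np.asarray(values, dtype=float)
    if not enabled:
        return np.ones(len(values), dtype=bool)
    return values <= np.percentile(values, percentile)


def binarize(values: np.ndarray) -> np.ndarray:
    """Median split into balanced classes low=0 / high=1.

    Samples are ranked (stable order for ties, so values tied at the median
    alternate between classes) and the lower half becomes class 0.  Class
    sizes differ by at most 1 for odd n.  All-identical values carry no
    information and raise ValueError.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to binarize")
    if np.all(values == values[0]):
        raise ValueError("uninformative feature: all values identical")
    order = np.argsort(values, kind="stable")
    classes = np.empty(n, dtype=int)
    classes[order[: n // 2]] = 0
    classes[order[n // 2:]] = 1
    return classes


def zscore(X: np.ndarray) -> np.ndarray:
    """Column-wise standardisation to zero mean and unit (population) SD."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column: degenerate parameters")
    return (X - X.mean(axis=0)) / sd


def knn_predict(
    train_X: np.ndarray,
    train_c: np.ndarray,
    test_X: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority-vote k-nearest-neighbour classification (Euclidean).

    Deterministic by construction: neighbours at equal distance are ordered
    by training-row index, and a tied vote falls back to the single nearest
    neighbour's class.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_c = np.asarray(train_c)
    n_train = train_X.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds {n_train} training rows")
    d = cdist(test_X, train_X)
    idx = np.arange(n_train)
    pred = np.empty(test_X.shape[0], dtype=train_c.dtype)
    for i, row in enumerate(d):
        order = np.lexsort((idx, row))  # distance, then stable index
        neigh = train_c[order[:k]]
        ones = int(np.sum(neigh == 1))
        if 2 * ones > k:
            pred[i] = 1
        elif 2 * ones < k:
            pred[i] = 0
        else:
            pred[i] = train_c[order[0]]
    return pred


def prediction_error(pred: np.ndarray, true: np.ndarray) -> float:
    """Misclassification fraction: #incorrect / #all, in [0, 1]."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true) or len(pred) == 0:
        raise ValueError("need equal-length non-empty label vectors")
    return float(np.mean(pred != true))


@dataclass
class AssociationResult:
    """Outcome of the kNN-vs-random significance procedure for one feature."""

    feature: str
    region_class: str
    ks: tuple[int, ...]
    per_k: dict[int, dict] = field(default_factory=dict)
    n_significant_k: int = 0
    significant: bool = False
    alpha: float = 1e-7
    n_regions: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, d in self.per_k.items():
            rows.append({"k": k, **{key: d[key] for key in (
                "true_mean", "true_q25", "true_q75", "random_mean",
                "random_q25", "random_q75", "p_value", "frac_true_below_half",
                "passed")}})
        return pd.DataFrame(rows)


def _stratified_split(
    classes: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified random train/test index split."""
    train_idx, test_idx = [], []
    for c in np.unique(classes):
        members = np.flatnonzero(classes == c)
        rng.shuffle(members)
        n_test = max(1, int(round(test_fraction * len(members))))
        n_test = min(n_test, len(members) - 1)  # keep both sides non-empty
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def significance_test(
    X: np.ndarray,
    classes: np.ndarray,
    ks: Sequence[int] = DEFAULT_KS,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    alpha: float = 1e-7,
    seed: int | np.random.Generator = 0,
    min_significant_k: int = 3,
    feature: str = "",
    region_class: str = "",
) -> AssociationResult:
    """kNN-vs-shuffled-labels association test on prepared inputs.

    ``X`` must already be filtered and z-scored and ``classes`` balanced
    (see :func:`feature_association_test` for the full pipeline).  For every
    k and repeat, the data are split into stratified train/test parts; a kNN
    model trained on the true labels and one trained on labels shuffled
    within the training set are both scored on the test part.  A k passes
    when a one-sided Welch t-test finds the true errors smaller than the
    random ones at level ``alpha`` AND at least 90% of the true errors fall
    below 0.5 (an unbiased coin).  The association is significant when at
    least ``min_significant_k`` of the evaluated k pass.

    Fully reproducible: a single integer seed fixes every split and shuffle.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if X.shape[0] != len(classes):
        raise ValueError("X and classes disagree in length")
    if len(np.unique(classes)) < 2:
        raise ValueError("need both classes present")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    result = AssociationResult(
        feature=feature, region_class=region_class, ks=tuple(ks),
        alpha=alpha, n_regions=X.shape[0],
    )
    for k in ks:
        true_errs = np.empty(n_repeats)
        rand_errs = np.empty(n_repeats)
        for rep in range(n_repeats):
            tr, te = _stratified_split(classes, test_fraction, rng)
            if k > len(tr):
                raise ValueError(
                    f"k={k} exceeds training size {len(tr)}; "
                    "reduce k or test_fraction"
                )
            shuffled = rng.permutation(classes[tr])
            true_errs[rep] = prediction_error(
                knn_predict(X[tr], classes[tr], X[te], k), classes[te])
            rand_errs[rep] = prediction_error(
                knn_predict(X[tr], shuffled, X[te], k), classes[te])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(
                true_errs, rand_errs, equal_var=False, alternative="less"
            ).pvalue
        if not np.isfinite(p):  # zero variance in both samples
            p = 0.0 if true_errs.mean() < rand_errs.mean() else 1.0
        frac_below = float(np.mean(true_errs < 0.5))
        passed = bool(p < alpha and frac_below >= 0.9)
        result.per_k[k] = {
            "true_mean": float(true_errs.mean()),
            "true_q25": float(np.quantile(true_errs, 0.25)),
            "true_q75": float(np.quantile(true_errs, 0.75)),
            "random_mean": float(rand_errs.mean()),
            "random_q25": float(np.quantile(rand_errs, 0.25)),
            "random_q75": float(np.quantile(rand_errs, 0.75)),
            "p_value": float(p),
            "frac_true_below_half": frac_below,
            "passed": passed,
            "true_errors": true_errs,
            "random_errors": rand_errs,
        }
    result.n_significant_k = sum(d["passed"] for d in result.per_k.values())
    result.significant = result.n_significant_k >= min_significant_k
    return result


def feature_association_test(
    params: pd.DataFrame,
    feature_values: pd.Series | np.ndarray,
    feature: str = "",
    region_class: str = "",
    trim: bool = True,
    ks: Sequence[int] = DEFAULT_KS,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    alpha: float = 1e-7,
    seed: int = 0,
    min_significant_k: int = 3,
) -> AssociationResult:
    """Full feature-association pipeline on a fit table.

    ``params`` needs columns m, beta, theta (rows already range-filtered).
    The feature is optionally trimmed to its lower 95th percentile, median-
    split into balanced classes, the parameter triples are z-scored, and
    :func:`significance_test` is run.
    """
    X = params[["m", "beta", "theta"]].to_numpy(dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("feature values and parameter rows disagree")
    mask = trim_percentile(y, enabled=trim)
    X, y = X[mask], y[mask]
    classes = binarize(y)
    return significance_test(
        zscore(X), classes, ks=ks, n_repeats=n_repeats,
        test_fraction=test_fraction, alpha=alpha, seed=seed,
        min_significant_k=min_significant_k,
        feature=feature, region_class=region_class,
    )


def xr_model_correlation(
    fits: Mapping[str, KJMAParams],
    xr_values: Mapping[str, Mapping[float, float]],
    cpd_courses: Mapping[str, RepairTimeCourse] | None = None,
    xr_times: Sequence[float] = (5.0, 20.0, 60.0),
) -> dict:
    """Distance correlation of model-predicted repair rates against XR signal.

    For every region with a valid fit and every XR sampling time, the square
    root of the model rate (the sqrt damps the variance growth of large
    derivatives) is pooled against the XR value; the DC of the pooled vectors
    is the model score.  When CPD-derived time courses are supplied, a
    baseline DC is also computed from the data-only rate surrogate (finite
    differences), mapping the interval (0, 20] to the 5- and 20-minute XR
    samples and (20, 60] to the 60-minute one.

    Returns a dict with keys ``model_dc``, ``baseline_dc`` (None without
    courses), ``n_points`` and ``n_dropped`` (regions lacking a fit or XR
    values).
    """
    model_pred, baseline_pred, xr_obs, xr_obs_base = [], [], [], []
    n_dropped = 0
    for region_id, per_time in xr_values.items():
        params = fits.get(region_id)
        if params is None:
            n_dropped += 1
            continue
        course = cpd_courses.get(region_id) if cpd_courses else None
        surrogate = None
        if course is not None:
            rates = empirical_repair_rate(course)
            edges = np.concatenate(([0.0], course.times))
            surrogate = dict(zip(zip(edges[:-1], edges[1:]), rates))
        for t in xr_times:
            if t not in per_time:
                continue
            model_pred.append(np.sqrt(repair_rate(params, t)))
            xr_obs.append(per_time[t])
            if surrogate is not None:
                match = next(
                    (r for (lo, hi), r in surrogate.items() if lo < t <= hi),
                    None,
                )
                if match is not None:
                    baseline_pred.append(match)
                    xr_obs_base.append(per_time[t])
    out = {
        "model_dc": distance_correlation(model_pred, xr_obs),
        "baseline_dc": None,
        "n_points": len(xr_obs),
        "n_dropped": n_dropped,
    }
    if cpd_courses is not None and len(baseline_pred) >= 2:
        out["baseline_dc"] = distance_correlation(baseline_pred, xr_obs_base)
    return out
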