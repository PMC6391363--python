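"""Feature matrix, filtering, SFFS, SVM criterion and CI significance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from primeconflict.containers import ConditionAverages
from primeconflict.featselect import (FeatureMatrix, build_feature_matrix,
                                      criterion_seed, evaluate_cumulative,
                                      feature_to_channel_time, sffs,
                                      svm_criterion, ttest_filter,
                                      zscore_features, baseline_erp_predictability)

T_995_DF9 = 3.2498   # Student t table, 99% two-sided, 9 df


def make_averages(data, sfreq=256.0, t0_ms=-500.0, condition="incompatible"):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[2]
    times = t0_ms + np.arange(n_t) / sfreq * 1000.0
    return ConditionAverages(condition, tuple(range(data.shape[0])), data,
                             tuple(f"ch{i}" for i in range(data.shape[1])),
                             times, sfreq)


# ---------------------------------------------------------------------------
# feature matrix and latency mapping

def test_feature_matrix_dimensions_and_window():
    # 4 channels x [0, 1.5) s at 256 Hz -> 384 samples per channel
    n_t = 640
    avg = make_averages(np.zeros((3, 4, n_t)), t0_ms=-500.0)
    fm = build_feature_matrix(avg)
    assert fm.n_samples == 384
    assert fm.X.shape == (3, 4 * 384)
    assert fm.index_map["ms_after_target"].min() == 0.0
    assert fm.index_map["ms_after_target"].max() < 1500.0


def test_latency_mapping_reference_samples():
    ch = tuple(f"ch{i}" for i in range(60))
    el, t1, p1 = feature_to_channel_time(1, ch, 384)
    assert (round(t1, 1), round(p1, 1)) == (3.9, 63.9)
    el, t2, p2 = feature_to_channel_time(2, ch, 384)
    assert (round(t2, 1), round(p2, 1)) == (7.8, 67.8)
    el, t100, _ = feature_to_channel_time(100, ch, 384)
    assert round(t100, 1) == 390.6
    el, t0, p0 = feature_to_channel_time(0, ch, 384)
    assert (t0, p0) == (0.0, 60.0)


def test_index_map_bijective_over_all_features():
    ch = tuple(f"c{i}" for i in range(60))
    n_samples = 384
    avg = make_averages(np.zeros((2, 60, 500)), t0_ms=0.0)
    fm = build_feature_matrix(avg)
    assert fm.X.shape[1] == 60 * 384 == 23040
    idx = fm.index_map
    # vectorized inverse check over all 23040 indices
    ch_idx = idx["feature"] // n_samples
    samp = idx["feature"] % n_samples
    np.testing.assert_array_equal(idx["sample"], samp)
    np.testing.assert_allclose(idx["ms_after_target"], samp / 256.0 * 1000.0)
    np.testing.assert_allclose(idx["ms_after_prime"] - idx["ms_after_target"], 60.0)
    el, t, p = fm.feature_time(23039)
    assert el == fm.ch_names[59] and p - t == pytest.approx(60.0)


def test_negative_window_start_exposes_pre_target_features():
    avg = make_averages(np.zeros((2, 2, 600)), t0_ms=-500.0)
    fm = build_feature_matrix(avg, window_s=(-0.03125, 1.5))
    assert fm.index_map["ms_after_target"].min() == pytest.approx(-31.25)
    assert (fm.index_map["ms_after_target"] < 0).sum() == 2 * 8


# ---------------------------------------------------------------------------
# z-scoring and t-filter

def test_zscore_closed_form_and_idempotence():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    Xz, const = zscore_features(X)
    np.testing.assert_allclose(Xz[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)
    assert list(const) == [1]
    assert np.all(Xz[:, 1] == 0.0)
    Xzz, _ = zscore_features(Xz[:, :1])
    np.testing.assert_allclose(Xzz, Xz[:, :1], atol=1e-9)


def test_ttest_filter_separated_and_identical_columns(rng):
    n = 12
    labels = np.array([0] * 6 + [1] * 6)
    X = np.zeros((n, 2))
    X[labels == 1, 0] = 10.0
    X[:, 0] += rng.normal(0, 1e-3, n)      # tiny jitter
    X[:, 1] = np.tile([1.0, 2.0, 3.0], 4)  # identical distributions
    kept, p = ttest_filter(X, labels)
    assert list(kept) == [0]
    assert p[1] == pytest.approx(1.0)


def test_ttest_filter_null_rate_near_alpha(rng):
    """Type-I calibration: about 1% of 1000 null columns pass at alpha=0.01."""
    labels = np.array([0] * 30 + [1] * 30)
    X = rng.standard_normal((60, 1000))
    kept, _ = ttest_filter(X, labels, alpha=0.01)
    # binomial(1000, 0.01): central 99.9% within roughly [1, 23]
    assert 1 <= kept.size <= 23


def test_ttest_filter_input_validation():
    with pytest.raises(ValueError, match="2 classes"):
        ttest_filter(np.zeros((4, 2)), np.array([0, 0, 0, 0]))
    with pytest.raises(ValueError, match="at least 2"):
        ttest_filter(np.zeros((3, 2)), np.array([0, 0, 1]))


# ---------------------------------------------------------------------------
# SVM criterion

def test_svm_separable_clusters(rng):
    n = 40
    y = np.array([0] * 20 + [1] * 20)
    X = rng.normal(size=(n, 2)) + np.where(y[:, None] == 1, 6.0, 0.0)
    assert svm_criterion(X, y, folds=10, seed=0) >= 0.95


def test_svm_permuted_labels_at_chance(rng):
    """Null calibration: mean accuracy over 100 label permutations stays in
    the binomial band around 0.5."""
    X = rng.normal(size=(40, 2))
    accs = []
    for s in range(100):
        y = np.array([0] * 20 + [1] * 20)
        np.random.default_rng(s).shuffle(y)
        accs.append(svm_criterion(X, y, folds=10, seed=s))
    assert 0.4 <= np.mean(accs) <= 0.6


def test_svm_duplicated_feature_within_fold_noise(rng):
    y = np.array([0] * 20 + [1] * 20)
    X = rng.normal(size=(40, 2)) + np.where(y[:, None] == 1, 1.5, 0.0)
    base = svm_criterion(X, y, folds=10, seed=3)
    dup = svm_criterion(np.hstack([X, X[:, :1]]), y, folds=10, seed=3)
    # not an exact kernel invariance; must stay within fold-resampling noise
    assert abs(dup - base) <= 0.1


def test_svm_k_exceeding_class_size_raises():
    y = np.array([0] * 4 + [1] * 4)
    with pytest.raises(ValueError, match="exceeds"):
        svm_criterion(np.zeros((8, 1)), y, folds=5)


# ---------------------------------------------------------------------------
# SFFS

def test_sffs_finds_informative_column_first(rng):
    n = 40
    y = np.array([0] * 20 + [1] * 20)
    X = rng.normal(size=(n, 10))
    X[:, 4] += np.where(y == 1, 4.0, 0.0)   # one informative column among noise
    order, _, _ = sffs(X, y, max_k=3, seed=1)
    assert order[0] == 4


def test_sffs_brackets_between_sfs_and_exhaustive(rng):
    """On 6 candidates the recorded criterion at each cardinality is at least
    plain SFS and at most the exhaustive-subset optimum."""
    n = 30
    y = np.array([0] * 15 + [1] * 15)
    X = rng.normal(size=(n, 6))
    X[:, 1] += np.where(y == 1, 1.2, 0.0)
    X[:, 3] += np.where(y == 1, -0.9, 0.0)
    crit_cache = {}
    def crit(cols):
        key = tuple(sorted(cols))
        if key not in crit_cache:
            crit_cache[key] = svm_criterion(X[:, list(key)], y, folds=5, seed=7)
        return crit_cache[key]
    _, best_subsets, best_scores = sffs(X, y, criterion=crit, max_k=4)
    # plain-SFS oracle
    sfs_scores, chosen = {}, []
    for k in range(1, 5):
        cands = [(crit(tuple(chosen) + (j,)), j) for j in range(6) if j not in chosen]
        s, j = max(cands, key=lambda c: (c[0], -c[1]))
        chosen.append(j)
        sfs_scores[k] = s
    # exhaustive oracle
    for k in range(1, 5):
        exhaustive = max(crit(c) for c in itertools.combinations(range(6), k))
        assert sfs_scores[k] <= best_scores[k] + 1e-12
        assert best_scores[k] <= exhaustive + 1e-12
        assert len(best_subsets[k]) == k


def test_sffs_full_cardinality_reaches_full_set(rng):
    y = np.array([0] * 10 + [1] * 10)
    X = rng.normal(size=(20, 4))
    def crit(cols):
        return len(cols) / 10.0 + sum(cols) * 1e-4   # monotone, deterministic
    _, best_subsets, best_scores = sffs(X, y, criterion=crit, max_k=4)
    assert sorted(best_subsets[4]) == [0, 1, 2, 3]
    assert best_scores[4] == pytest.approx(crit((0, 1, 2, 3)))


def test_sffs_rejects_non_finite_criterion():
    X = np.zeros((10, 3))
    y = np.array([0] * 5 + [1] * 5)
    with pytest.raises(FloatingPointError):
        sffs(X, y, criterion=lambda cols: float("nan"), max_k=2)


def test_sffs_tie_breaks_to_lowest_index():
    X = np.zeros((10, 4))
    y = np.array([0] * 5 + [1] * 5)
    order, _, _ = sffs(X, y, criterion=lambda cols: 0.5, max_k=2)
    assert order[:2] == [0, 1]


# ---------------------------------------------------------------------------
# cumulative evaluation and confidence bounds

def test_ci_closed_form_against_t_table():
    accs = np.array([0.60, 0.62, 0.64, 0.66, 0.68, 0.70, 0.72, 0.74, 0.76, 0.78])
    from primeconflict.featselect import _t_interval
    m, lo, hi = _t_interval(accs, 0.99)
    sd = accs.std(ddof=1)
    half = T_995_DF9 * sd / np.sqrt(10)
    assert m == pytest.approx(0.69)
    assert lo == pytest.approx(0.69 - half, abs=1e-4)
    assert hi == pytest.approx(0.69 + half, abs=1e-4)


def test_zero_variance_folds_collapse_ci():
    from primeconflict.featselect import _t_interval
    m, lo, hi = _t_interval(np.full(10, 0.8), 0.99)
    assert (m, lo, hi) == (0.8, 0.8, 0.8)


def test_evaluate_cumulative_significance_rules(rng):
    n = 60
    y = np.array([0] * 30 + [1] * 30)
    X = rng.normal(size=(n, 3))
    X[:, 0] += np.where(y == 1, 5.0, 0.0)   # near-perfect single feature
    res = evaluate_cumulative(X, y, [0, 1, 2], k=10, seed=0)
    assert res.significant[0]                # CI above chance
    assert res.fold_accuracies.shape == (3, 10)
    assert np.all(res.ci_lower <= res.mean_accuracy + 1e-12)
    assert np.all(res.mean_accuracy <= res.ci_upper + 1e-12)
    # adding pure-noise features never yields a disjoint higher interval here
    assert not res.significant[1:].any()


def test_criterion_seed_differs_from_evaluation_seed():
    assert criterion_seed(0) != 0
    assert criterion_seed(1) != 1
    assert 0 <= criterion_seed(123456789) < 2 ** 31


def test_baseline_erp_predictability_machinery(rng):
    y = np.array([0] * 20 + [1] * 20)
    strong = rng.normal(size=(40, 6))
    strong[:, 2] += np.where(y == 1, 4.0, 0.0)
    res = baseline_erp_predictability(strong, y, k=10, seed=0)
    assert res.mean_accuracy[0] > 0.8 and res.significant[0]
    null = baseline_erp_predictability(rng.normal(size=(40, 6)), y, k=10, seed=0)
    assert 0.2 <= null.mean_accuracy[0] <= 0.8
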