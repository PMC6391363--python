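"""Data-driven predictive-feature discovery.

Pipeline: per-subject condition-average waveforms are unrolled into a
subjects x (channel, time point) matrix over [0, 1.5) s at 256 Hz,
z-scored per feature, screened with a two-sample t-test (p < 0.01), ordered
by sequential floating forward selection (SFFS) with a stratified
cross-validated RBF-SVM accuracy criterion, and evaluated cumulatively with
k = 10 folds.  A Student-t 99% confidence interval is placed on the k fold
accuracies at each cardinality; the first feature is significant when its
interval excludes chance (0.5), and each further feature adds significant
predictability when its interval is disjoint from the previous one.

Filtering and z-scoring on the full sample before cross-validation follow
the original protocol; ``nested=True`` re-fits the whole selection inside
every training fold and is the leakage-free choice for new data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import ConditionAverages
from .protocol import DEFAULT_PROTOCOL

__all__ = ["FeatureMatrix", "SelectionResult", "build_feature_matrix",
           "zscore_features", "ttest_filter", "sffs", "svm_criterion",
           "evaluate_cumulative", "feature_to_channel_time",
           "baseline_erp_predictability", "PredictiveFeatureModel"]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature matrix and index bookkeeping

@dataclass
class FeatureMatrix:
    """Subjects x (channel, time point) values for one prime condition.

    Feature index is channel-major: ``index = channel * n_samples + sample``.
    ``index_map`` carries electrode, sample, and latencies relative to both
    target onset and prime onset (always 60 ms apart at the canonical SOA).
    """

    X: np.ndarray
    subjects: tuple
    condition: str
    index_map: pd.DataFrame
    ch_names: tuple
    n_samples: int
    window_start_s: float
    sfreq: float
    soa_ms: float

    def feature_time(self, index: int):
        row = self.index_map.iloc[index]
        return row["electrode"], float(row["ms_after_target"]), float(row["ms_after_prime"])


def feature_to_channel_time(index: int, ch_names, n_samples: int,
                            window_start_s: float = 0.0, sfreq: float = 256.0,
                            soa_ms: float = 60.0):
    """Inverse of the feature index map: (electrode, ms after target, ms after prime)."""
    if not 0 <= index < len(ch_names) * n_samples:
        raise IndexError("feature index out of range")
    ch, samp = divmod(int(index), int(n_samples))
    ms_target = (window_start_s + samp / sfreq) * 1000.0
    return ch_names[ch], ms_target, ms_target + soa_ms


def build_feature_matrix(averages: ConditionAverages, window_s=(0.0, 1.5),
                         soa_ms: float = 60.0) -> FeatureMatrix:
    """Unroll condition averages into a feature matrix over the half-open window."""
    t = averages.times_ms / 1000.0
    mask = (t >= window_s[0] - 1e-9) & (t < window_s[1] - 1e-9)
    n_samples = int(mask.sum())
    data = averages.data[:, :, mask]
    X = data.reshape(data.shape[0], -1)
    ch = np.repeat(np.arange(len(averages.ch_names)), n_samples)
    samp = np.tile(np.arange(n_samples), len(averages.ch_names))
    ms_target = (window_s[0] + samp / averages.sfreq) * 1000.0
    index_map = pd.DataFrame({
        "feature": np.arange(X.shape[1]),
        "electrode": np.asarray(averages.ch_names)[ch],
        "sample": samp,
        "ms_after_target": ms_target,
        "ms_after_prime": ms_target + soa_ms,
    })
    return FeatureMatrix(X, averages.subjects, averages.condition, index_map,
                         averages.ch_names, n_samples, window_s[0],
                         averages.sfreq, soa_ms)


def zscore_features(X: np.ndarray):
    """Per-column standardization with the population SD convention.

    Returns ``(Xz, constant_columns)``; constant columns map to all zeros.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)            # ddof=0: population SD
    constant = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xz = (X - mu) / sd_safe
    Xz[:, constant] = 0.0
    if constant.size:
        log.warning("%d constant feature columns zeroed", constant.size)
    return Xz, constant


def ttest_filter(X: np.ndarray, labels: np.ndarray, alpha: float = 0.01):
    """Two-sided independent-samples t per column; keep p < alpha.

    Returns ``(candidate_indices, pvalues_all_columns)``.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("labels must have exactly 2 classes")
    a, b = X[labels == groups[0]], X[labels == groups[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("both groups need at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    return np.flatnonzero(p < alpha), p


# ---------------------------------------------------------------------------
# wrapper selection

def svm_criterion(X: np.ndarray, labels: np.ndarray, folds: int = 10,
                  C: float = 1.0, gamma="scale", seed: int = 0) -> float:
    """Mean stratified k-fold accuracy of an RBF-kernel SVM (deterministic per seed)."""
    return float(np.mean(_fold_accuracies(X, labels, folds, C, gamma, seed)))


def _make_splits(labels, folds, seed):
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"k={folds} exceeds the smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    return list(skf.split(np.zeros((len(labels), 1)), labels))


def _fold_accuracies(X, labels, folds, C, gamma, seed, splits=None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if splits is None:
        splits = _make_splits(labels, folds, seed)
    accs = []
    for tr, te in splits:
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[tr], labels[tr])
        accs.append(clf.score(X[te], labels[te]))
    return np.asarray(accs)


def criterion_seed(seed: int) -> int:
    """Fixed internal substream for the SFFS wrapper criterion.

    The selection criterion and the final k-fold evaluation must not share a
    fold partition: re-using the partition whose accuracy the wrapper just
    maximized would evaluate the selection on its own objective.  The
    evaluation divides the data afresh with the caller's seed, the wrapper
    with this derived one.
    """
    return (1103515245 * int(seed) + 12345) % (2 ** 31)


def sffs(X: np.ndarray, labels: np.ndarray, criterion=None, max_k: int = 20,
         seed: int = 0, folds: int = 10, C: float = 1.0, gamma="scale"):
    """Sequential floating forward selection.

    Forward steps add the criterion-maximizing feature (ties break to the
    lowest column index); after each forward step, backward steps remove a
    feature whenever that strictly improves the best recorded criterion at
    the smaller cardinality.  Returns ``(order, best_subsets, best_scores)``
    where ``order`` is the nested chain read off the per-cardinality best
    subsets and ``best_subsets[c]``/``best_scores[c]`` (1-based) are the best
    subset and criterion value recorded at cardinality ``c``.

    ``criterion`` is a callable ``(subset_columns) -> float``; the default is
    the stratified k-fold RBF-SVM accuracy with a fixed internal seed.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if n_feat == 0:
        raise ValueError("no candidate features")
    max_k = min(max_k, n_feat)
    if criterion is None:
        splits = _make_splits(labels, folds, seed)

        def criterion(cols):
            return float(np.mean(_fold_accuracies(
                X[:, list(cols)], labels, folds, C, gamma, seed, splits=splits)))

    cache: dict[tuple, float] = {}

    def scored(cols):
        key = tuple(sorted(cols))
        if key not in cache:
            value = criterion(cols)
            if not np.isfinite(value):
                raise FloatingPointError("non-finite selection criterion")
            cache[key] = value
        return cache[key]

    best_subsets: dict[int, tuple] = {}
    best_scores: dict[int, float] = {}
    current: list[int] = []

    def record(subset, score):
        k = len(subset)
        if k and (k not in best_scores or score > best_scores[k]):
            best_subsets[k] = tuple(subset)
            best_scores[k] = score

    while len(current) < max_k:
        # forward: add the best remaining feature
        cands = [j for j in range(n_feat) if j not in current]
        scores = [scored(tuple(current) + (j,)) for j in cands]
        jbest = cands[int(np.argmax(scores))]      # argmax -> lowest index on ties
        current.append(jbest)
        record(current, scores[cands.index(jbest)])
        # floating backward: drop while it strictly improves the smaller cardinality
        while len(current) > 2:
            sub_scores = []
            for j in current:
                reduced = tuple(f for f in current if f != j)
                sub_scores.append((scored(reduced), j, reduced))
            best = max(sub_scores, key=lambda s: s[0])
            k_small = len(current) - 1
            if best[1] != current[-1] and best[0] > best_scores.get(k_small, -np.inf):
                current = list(best[2])
                record(current, best[0])
            else:
                break

    order = _nested_order(best_subsets, max_k)
    return order, best_subsets, best_scores


def _nested_order(best_subsets: dict, max_k: int) -> list:
    """Read a feature ordering off the per-cardinality best subsets.

    When floating steps make consecutive best subsets non-nested, newly
    appearing features are appended in index order, so ``order[:c]`` always
    contains exactly the features first seen by cardinality ``c``.
    """
    order: list[int] = []
    for k in range(1, max_k + 1):
        subset = best_subsets.get(k)
        if subset is None:
            continue
        for j in subset:
            if j not in order:
                order.append(j)
    return order


# ---------------------------------------------------------------------------
# cumulative evaluation and significance

@dataclass
class SelectionResult:
    """Ordered features with per-cardinality predictability and 99% CIs."""

    condition: str
    features: list                      # column indices into the candidate matrix
    feature_table: pd.DataFrame         # electrode / latency / p-value per feature
    fold_accuracies: np.ndarray         # (n_cardinalities, k)
    mean_accuracy: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    significant: np.ndarray             # bool per cardinality
    k: int
    level: float
    chance: float = 0.5

    def __post_init__(self):
        if np.any(self.fold_accuracies < 0) or np.any(self.fold_accuracies > 1):
            raise ValueError("fold accuracies must lie in [0, 1]")
        if np.any(self.ci_lower > self.mean_accuracy + 1e-12) or \
           np.any(self.ci_upper < self.mean_accuracy - 1e-12):
            raise ValueError("confidence bounds must bracket the mean")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_table(self) -> pd.DataFrame:
        tab = self.feature_table.copy()
        tab["mean_predictability_pct"] = 100.0 * self.mean_accuracy
        tab["ci_lower_pct"] = 100.0 * self.ci_lower
        tab["ci_upper_pct"] = 100.0 * self.ci_upper
        tab["significant"] = self.significant
        return tab

    def summary(self) -> str:
        lines = [f"Predictive-feature discovery - {self.condition} condition",
                 f"k = {self.k} folds, {int(self.level * 100)}% confidence bounds, "
                 f"chance = {self.chance:.2f}",
                 f"significant features: {self.n_significant}", ""]
        hdr = (f"{'#':>3} {'electrode':>9} {'ms/prime':>9} {'ms/target':>9} "
               f"{'pred%':>7} {'CI':>17} {'filter p':>9} {'sig':>4}")
        lines.append(hdr)
        for i, row in self.to_table().iterrows():
            lines.append(
                f"{i + 1:>3} {row['electrode']:>9} {row['ms_after_prime']:>9.1f} "
                f"{row['ms_after_target']:>9.1f} {row['mean_predictability_pct']:>7.2f} "
                f"[{row['ci_lower_pct']:>6.2f}, {row['ci_upper_pct']:>6.2f}] "
                f"{row['filter_p']:>9.5f} {'*' if row['significant'] else '':>4}")
        return "\n".join(lines)


def _t_interval(fold_accs: np.ndarray, level: float):
    k = fold_accs.size
    mean = float(fold_accs.mean())
    sd = float(fold_accs.std(ddof=1))
    if sd == 0:
        return mean, mean, mean
    half = stats.t.ppf(1.0 - (1.0 - level) / 2.0, k - 1) * sd / np.sqrt(k)
    return mean, mean - half, mean + half


def evaluate_cumulative(X: np.ndarray, labels: np.ndarray, ordered_features,
                        k: int = 10, level: float = 0.99, seed: int = 0,
                        C: float = 1.0, gamma="scale", condition: str = "",
                        feature_table: pd.DataFrame | None = None,
                        chance: float = 0.5) -> SelectionResult:
    """k-fold predictability of the first c features for c = 1..len(order).

    Significance: cardinality 1 iff its CI lower bound exceeds chance;
    cardinality c > 1 iff its CI is disjoint from the CI at c - 1.
    """
    ordered_features = list(ordered_features)
    if not ordered_features:
        raise ValueError("no features to evaluate")
    folds, means, los, his = [], [], [], []
    for c in range(1, len(ordered_features) + 1):
        accs = _fold_accuracies(X[:, ordered_features[:c]], labels, k, C, gamma, seed)
        m, lo, hi = _t_interval(accs, level)
        folds.append(accs)
        means.append(m)
        los.append(lo)
        his.append(hi)
    sig = np.zeros(len(means), dtype=bool)
    sig[0] = los[0] > chance
    for c in range(1, len(means)):
        sig[c] = (los[c] > his[c - 1]) or (his[c] < los[c - 1])
    if feature_table is None:
        feature_table = pd.DataFrame({"feature": ordered_features})
    return SelectionResult(condition, ordered_features, feature_table.reset_index(drop=True),
                           np.asarray(folds), np.asarray(means), np.asarray(los),
                           np.asarray(his), sig, k, level, chance)


def baseline_erp_predictability(erp_features: np.ndarray, labels: np.ndarray,
                                k: int = 10, seed: int = 0, level: float = 0.99,
                                C: float = 1.0, gamma="scale") -> SelectionResult:
    """Same SVM/CV machinery applied to classical ERP mean amplitudes.

    ``erp_features`` is subjects x components (e.g. condition-difference mean
    amplitudes); all columns enter as one feature set.
    """
    Xz, _ = zscore_features(np.asarray(erp_features, dtype=float))
    accs = _fold_accuracies(Xz, labels, k, C, gamma, seed)
    m, lo, hi = _t_interval(accs, level)
    tab = pd.DataFrame({"feature": [0], "electrode": ["(ERP set)"],
                        "ms_after_target": [np.nan], "ms_after_prime": [np.nan],
                        "filter_p": [np.nan]})
    return SelectionResult("erp_baseline", [0], tab, np.asarray([accs]),
                           np.asarray([m]), np.asarray([lo]), np.asarray([hi]),
                           np.asarray([lo > 0.5]), k, level)


# ---------------------------------------------------------------------------
# model-style front end

class PredictiveFeatureModel:
    """Group-membership predictability from condition-average EEG.

    statsmodels-style: construct from data, call :meth:`fit`, inspect the
    returned :class:`SelectionResult` (and its ``summary()``).

    Parameters
    ----------
    averages : ConditionAverages
        Per-subject waveforms for one prime-compatibility condition.
    groups : array-like or pd.Series
        Binary group labels per subject (e.g. small/large PCE), aligned with
        ``averages.subjects``.
    protocol : ProtocolSpec
    nested : bool
        If True, z-scoring, filtering and SFFS are re-fit inside each
        training fold (leakage-free); the protocol default is False,
        selecting on the full sample.
    """

    def __init__(self, averages: ConditionAverages, groups, protocol=None,
                 nested: bool = False):
        self.protocol = protocol or DEFAULT_PROTOCOL
        self.averages = averages
        if isinstance(groups, pd.Series):
            groups = groups.reindex(list(averages.subjects)).to_numpy()
        self.groups = np.asarray(groups)
        if len(self.groups) != len(averages.subjects):
            raise ValueError("groups must align with averages.subjects")
        self.nested = nested
        self.matrix = build_feature_matrix(
            averages, window_s=self.protocol.feature_window_s,
            soa_ms=self.protocol.soa_ms)

    def fit(self, seed: int = 0, max_k: int | None = None) -> SelectionResult:
        p = self.protocol
        max_k = max_k or p.max_features
        if self.nested:
            return self._fit_nested(seed, max_k)
        Xz, _ = zscore_features(self.matrix.X)
        cand, pvals = ttest_filter(Xz, self.groups, alpha=p.filter_alpha)
        if cand.size == 0:
            log.info("no features pass the p<%.3g filter", p.filter_alpha)
            return _empty_result(self.matrix.condition, p)
        order_local, _, _ = sffs(Xz[:, cand], self.groups,
                                 max_k=min(max_k, cand.size),
                                 seed=criterion_seed(seed),
                                 folds=p.k_folds, C=p.svm_c, gamma=p.svm_gamma)
        order = [int(cand[j]) for j in order_local][:max_k]
        tab = self.matrix.index_map.iloc[order][
            ["feature", "electrode", "ms_after_target", "ms_after_prime"]].copy()
        tab["filter_p"] = pvals[order]
        return evaluate_cumulative(Xz, self.groups, order, k=p.k_folds,
                                   level=p.ci_level, seed=seed, C=p.svm_c,
                                   gamma=p.svm_gamma,
                                   condition=self.matrix.condition,
                                   feature_table=tab)

    def _fit_nested(self, seed: int, max_k: int):
        """Leakage-free variant: the full selection runs inside each training
        fold and the fold's own subset is scored on its held-out subjects."""
        p = self.protocol
        X = self.matrix.X
        y = self.groups
        skf = StratifiedKFold(n_splits=p.k_folds, shuffle=True,
                              random_state=int(seed) % (2**31))
        per_card = []
        for tr, te in skf.split(X, y):
            mu, sd = X[tr].mean(0), X[tr].std(0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
            cand, _ = ttest_filter(Xtr, y[tr], alpha=p.filter_alpha)
            if cand.size == 0:
                per_card.append([np.mean(y[te] == stats.mode(y[tr]).mode)] * max_k)
                continue
            inner_folds = min(p.k_folds, np.bincount(
                pd.factorize(y[tr])[0]).min())
            order_local, _, _ = sffs(Xtr[:, cand], y[tr],
                                     max_k=min(max_k, cand.size),
                                     seed=criterion_seed(seed),
                                     folds=inner_folds, C=p.svm_c, gamma=p.svm_gamma)
            row = []
            for c in range(1, max_k + 1):
                cols = cand[order_local[:min(c, len(order_local))]]
                clf = SVC(kernel="rbf", C=p.svm_c, gamma=p.svm_gamma)
                clf.fit(Xtr[:, cols], y[tr])
                row.append(clf.score(Xte[:, cols], y[te]))
            per_card.append(row)
        folds = np.asarray(per_card).T          # (max_k, k)
        means, los, his = [], [], []
        for accs in folds:
            m, lo, hi = _t_interval(accs, p.ci_level)
            means.append(m)
            los.append(lo)
            his.append(hi)
        sig = np.zeros(len(means), dtype=bool)
        sig[0] = los[0] > 0.5
        for c in range(1, len(means)):
            sig[c] = (los[c] > his[c - 1]) or (his[c] < los[c - 1])
        tab = pd.DataFrame({"feature": np.arange(len(means)),
                            "electrode": ["(per-fold)"] * len(means),
                            "ms_after_target": np.nan, "ms_after_prime": np.nan,
                            "filter_p": np.nan})
        return SelectionResult(self.matrix.condition + " (nested)",
                               list(range(len(means))), tab, folds,
                               np.asarray(means), np.asarray(los), np.asarray(his),
                               sig, p.k_folds, p.ci_level)


def _empty_result(condition, protocol) -> SelectionResult:
    tab = pd.DataFrame(columns=["feature", "electrode", "ms_after_target",
                                "ms_after_prime", "filter_p"])
    z = np.zeros((0, protocol.k_folds))
    e = np.zeros(0)
    return SelectionResult(condition, [], tab, z, e, e.copy(), e.copy(),
                           np.zeros(0, dtype=bool), protocol.k_folds,
                           protocol.ci_level)
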