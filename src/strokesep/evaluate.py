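"""Separability harness: repeated k-fold accuracy over a classifier panel.

Separability of candidate regions is measured as cross-validated
classification accuracy: 10 common classifier families x the feature sets
surviving each information-gain threshold x stratified 4-fold cross
validation repeated (default 100 times), with features standardized inside
each training fold. A region and its mirrored counterpart share a subject
and slice, so paired splitting keeps them in the same fold — splitting them
would leak subject identity and inflate accuracy.

The report carries the full classifier x threshold accuracy grid, the
per-threshold averages over classifiers, the overall average (mean of the
per-threshold averages over thresholds >= 0.1 — thresholds in the range
where screening has actually removed noise), and the single best cell.
Because the feature screen runs on the full table before cross-validation,
post-selection accuracies are optimistically biased; the report says so.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .infogain import DEFAULT_THRESHOLDS, IGResult, LabeledFeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVReport",
    "CLASSIFIER_FAMILIES",
    "build_classifier",
    "run_cv",
    "run_matrix",
    "run_three_experiments",
]

CLASSIFIER_FAMILIES = (
    "multilayer_perceptron",
    "decision_tree",
    "random_forest",
    "adaboost",
    "gradient_boosting",
    "bagging",
    "bernoulli_naive_bayes",
    "gaussian_naive_bayes",
    "support_vector_machine",
    "k_nearest_neighbor",
)


def build_classifier(family: str, seed: int):
    """Fixed, documented hyperparameter defaults; the families are the panel,
    not the tuning target."""
    if family == "multilayer_perceptron":
        return MLPClassifier(hidden_layer_sizes=(100,), max_iter=200, random_state=seed)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if family == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if family == "bagging":
        return BaggingClassifier(n_estimators=100, random_state=seed)
    if family == "bernoulli_naive_bayes":
        # features are median-binarized per training fold before fitting
        return BernoulliNB(binarize=None)
    if family == "gaussian_naive_bayes":
        return GaussianNB()
    if family == "support_vector_machine":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if family == "k_nearest_neighbor":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass(frozen=True)
class CVConfig:
    folds: int = 4
    repeats: int = 100
    seed: int = 0
    paired_split: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass(frozen=True)
class CVReport:
    grid: pd.DataFrame  # classifiers x thresholds, mean accuracy
    threshold_averages: dict[float, float]
    overall_average: float  # mean of per-threshold averages, thresholds >= 0.1
    overall_average_all_thresholds: float
    best_accuracy: float
    best_classifier: str
    best_threshold: float
    balanced: dict[float, float] = field(default_factory=dict)  # extension, clearly marked
    note: str = (
        "Feature screening used the full table before cross-validation; "
        "post-selection accuracies are optimistically biased."
    )

    def to_dict(self) -> dict:
        return {
            "grid": {c: {str(t): float(self.grid.loc[c, t]) for t in self.grid.columns}
                     for c in self.grid.index},
            "threshold_averages": {str(t): float(v) for t, v in self.threshold_averages.items()},
            "overall_average": float(self.overall_average),
            "overall_average_all_thresholds": float(self.overall_average_all_thresholds),
            "best_accuracy": float(self.best_accuracy),
            "best_classifier": self.best_classifier,
            "best_threshold": float(self.best_threshold),
            "balanced_accuracy_extension": {str(t): float(v) for t, v in self.balanced.items()},
            "note": self.note,
        }


def _make_splits(
    y: np.ndarray,
    pairing_id: np.ndarray | None,
    folds: int,
    paired: bool,
    rng: np.random.Generator,
    max_tries: int = 20,
):
    """Fold index pairs via scikit-learn's splitters; paired splitting keeps a
    region and its mirror (same group) in one fold. Degenerate splits (a
    training fold missing a class) are resampled and logged."""
    n = len(y)
    use_groups = (
        paired and pairing_id is not None and len(pd.unique(pairing_id)) >= folds
    )
    for _ in range(max_tries):
        rs = int(rng.integers(2**31 - 1))
        if use_groups:
            splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=rs)
            splits = list(splitter.split(np.zeros((n, 1)), y, groups=pairing_id))
        else:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            splits = list(splitter.split(np.zeros((n, 1)), y))
        if all(len(np.unique(y[tr])) == 2 and len(te) > 0 for tr, te in splits):
            return splits
        log.debug("degenerate fold encountered, resampling the split")
    raise RuntimeError("could not draw a non-degenerate cross-validation split")


def run_cv(
    table: LabeledFeatureTable,
    feature_set: list[str],
    family: str,
    config: CVConfig,
    return_balanced: bool = False,
):
    """Mean accuracy of one classifier on one feature set.

    Standardization (and, for the Bernoulli naive Bayes, median
    binarization) is fit on each training fold only. Accuracy is the pooled
    fraction correct per test fold, averaged over all folds of all repeats.
    Deterministic per config seed.
    """
    if not feature_set:
        raise ValueError("empty feature set")
    x_all = table.features[feature_set].to_numpy(dtype=float)
    y = table.y
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, zlib.crc32(family.encode()) % 2**31))
    )
    accs, baccs = [], []
    for _ in range(config.repeats):
        splits = _make_splits(
            y, table.pairing_id, config.folds, config.paired_split, rng
        )
        for train, test in splits:
            xtr, xte = x_all[train], x_all[test]
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
            if family == "bernoulli_naive_bayes":
                med = np.median(xtr, axis=0)
                xtr = (xtr > med).astype(float)
                xte = (xte > med).astype(float)
            clf = build_classifier(family, seed=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(xtr, y[train])
                pred = clf.predict(xte)
            accs.append(float(np.mean(pred == y[test])))
            if return_balanced:
                b = [np.mean(pred[y[test] == c] == c) for c in np.unique(y[test])]
                baccs.append(float(np.mean(b)))
    if return_balanced:
        return float(np.mean(accs)), float(np.mean(baccs))
    return float(np.mean(accs))


def run_matrix(
    table: LabeledFeatureTable,
    ig_result: IGResult,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES,
    config: CVConfig | None = None,
) -> CVReport:
    """The full classifier x threshold accuracy grid for one pairing.

    Thresholds with no surviving feature are skipped and logged (they appear
    as absent columns, like blank cells in a results table).
    """
    config = config if config is not None else CVConfig()
    active = []
    for t in thresholds:
        if len(ig_result.select(float(t))) == 0:
            log.info("threshold %.2f has no surviving features; skipped", t)
        else:
            active.append(float(t))
    if not active:
        raise ValueError("no threshold has surviving features")
    grid = pd.DataFrame(index=list(classifiers), columns=active, dtype=float)
    balanced: dict[float, float] = {}
    for t in active:
        feats = ig_result.select(t)
        bacc_cells = []
        for fam in classifiers:
            acc, bacc = run_cv(table, feats, fam, config, return_balanced=True)
            grid.loc[fam, t] = acc
            bacc_cells.append(bacc)
        balanced[t] = float(np.mean(bacc_cells))
    thr_avg = {t: float(grid[t].mean()) for t in active}
    nonzero = [t for t in active if t >= 0.1]
    overall = float(np.mean([thr_avg[t] for t in nonzero])) if nonzero else float("nan")
    overall_all = float(np.mean(list(thr_avg.values())))
    best_t = max(active, key=lambda t: grid[t].max())
    best_c = grid[best_t].idxmax()
    return CVReport(
        grid=grid,
        threshold_averages=thr_avg,
        overall_average=overall,
        overall_average_all_thresholds=overall_all,
        best_accuracy=float(grid[best_t].max()),
        best_classifier=str(best_c),
        best_threshold=float(best_t),
        balanced=balanced,
    )


def run_three_experiments(
    tables: dict[str, LabeledFeatureTable],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES,
    config: CVConfig | None = None,
    k_bins: int = 10,
) -> dict[str, dict]:
    """Screen + evaluate each pairing table (keys: lesion_vs_mirror,
    normal_vs_mirror, lesion_vs_normal). Returns per-pairing dicts with the
    IG result and the CV report."""
    from .infogain import screen_features

    out = {}
    for name, table in tables.items():
        ig = screen_features(table, thresholds=thresholds, k_bins=k_bins)
        report = run_matrix(table, ig, thresholds=thresholds, classifiers=classifiers, config=config)
        out[name] = {"ig": ig, "report": report}
    return out
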