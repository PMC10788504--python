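"""Trial decoding: ATM features versus a common-spatial-patterns baseline.

Both pipelines share the same stratified 80/20 shuffle splits and the same
linear-kernel SVM; they differ only in the features:

* ATM — each trial's avalanche transition matrix, flattened (directed, with
  diagonal). The binarization threshold is selected per split by inner
  cross-validation on the training trials only.
* CSP — spatial filters from the generalized eigendecomposition of the two
  class covariance matrices (Ledoit-Wolf shrinkage), the classic
  motor-imagery feature extractor; log-variance of the 8 extreme modes.

Per-subject comparison: paired t-test and Wilcoxon signed-rank over the
per-split accuracies, BH-corrected across subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import ttest_rel, wilcoxon
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .avalanches import EpochedSourceData, extract_trial_atms
from .permutation import bh_correct

logger = logging.getLogger(__name__)

__all__ = [
    "csp_fit",
    "csp_features",
    "atm_features",
    "select_atm_threshold",
    "evaluate_pipelines",
    "compare_pipelines",
    "DecodingResult",
]

DEFAULT_THRESHOLD_GRID = (2.5, 3.0, 3.5, 4.0)
_VAR_FLOOR = np.finfo(float).eps


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _class_covariance(trials: np.ndarray, shrinkage: str | None = "ledoit") -> np.ndarray:
    """Average covariance of a class: trials demeaned over time, concatenated.

    ``shrinkage="ledoit"`` applies Ledoit-Wolf shrinkage toward a scaled
    identity (needed for short trials); None uses the raw covariance.
    """
    demeaned = trials - trials.mean(axis=2, keepdims=True)
    samples = np.concatenate(demeaned, axis=1).T  # (trials*samples, regions)
    if shrinkage == "ledoit":
        cov, _ = ledoit_wolf(samples, assume_centered=True)
        return cov
    return samples.T @ samples / samples.shape[0]


def csp_fit(
    trials: np.ndarray,
    labels: np.ndarray,
    n_modes: int = 8,
    shrinkage: str | None = "ledoit",
) -> np.ndarray:
    """Common spatial patterns: filters (n_modes x regions).

    Solves the generalized eigenproblem C1 w = lambda (C1 + C2) w for the two
    class covariances and keeps the n_modes/2 top and n_modes/2 bottom
    eigenvalue extremes (the most discriminative variance ratios). Filter
    signs are fixed so the largest-magnitude coefficient is positive.
    """
    trials = np.asarray(trials, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"CSP needs exactly 2 classes; got {classes.tolist()}")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 trials per class")
    c1 = _class_covariance(trials[labels == classes[0]], shrinkage)
    c2 = _class_covariance(trials[labels == classes[1]], shrinkage)
    try:
        eigvals, eigvecs = eigh(c1, c1 + c2)
    except np.linalg.LinAlgError as err:
        raise SingularCovarianceError(
            "class covariance is singular; use shrinkage='ledoit' or reduce regions"
        ) from err
    n_regions = c1.shape[0]
    n_modes = min(n_modes, n_regions)
    n_low = n_modes // 2
    n_high = n_modes - n_low
    order = np.argsort(eigvals)
    pick = np.concatenate([order[:n_low], order[-n_high:][::-1]])
    filters = eigvecs[:, pick].T
    sign = np.sign(filters[np.arange(len(pick)), np.abs(filters).argmax(axis=1)])
    sign[sign == 0] = 1.0
    return filters * sign[:, None]


def csp_features(trials: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Log-variance of each spatially filtered time course, per trial.

    Log of the mode power is the standard conditioning transform; degenerate
    (zero) variances are floored at machine epsilon and logged.
    """
    trials = np.asarray(trials, dtype=float)
    filtered = np.einsum("mr,trs->tms", filters, trials)
    var = filtered.var(axis=2)
    n_floored = int((var <= _VAR_FLOOR).sum())
    if n_floored:
        logger.warning("%d degenerate mode variances floored at eps", n_floored)
    return np.log(np.maximum(var, _VAR_FLOOR))


def atm_features(trial_atms: np.ndarray, has_avalanches: np.ndarray | None = None) -> np.ndarray:
    """Flatten per-trial ATMs row-major into (n_trials, regions^2) vectors.

    Trials without avalanches keep all-zero vectors (flagged via a warning).
    """
    mats = np.asarray(trial_atms, dtype=float)
    if mats.ndim != 3:
        raise ValueError("trial_atms must be (trials, regions, regions)")
    if has_avalanches is not None and not np.all(has_avalanches):
        logger.warning(
            "%d trials without avalanches enter as all-zero feature vectors",
            int((~np.asarray(has_avalanches, dtype=bool)).sum()),
        )
    return mats.reshape(mats.shape[0], -1)


def _make_svm() -> SVC:
    # linear kernel, C = 1: maximum-margin classifier without tuning
    return SVC(kernel="linear", C=1.0)


def _inner_cv_accuracy(
    features: np.ndarray, labels: np.ndarray, n_splits: int, rng_seed: int
) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
    accs = []
    for tr, te in skf.split(features, labels):
        clf = _make_svm().fit(features[tr], labels[tr])
        accs.append(clf.score(features[te], labels[te]))
    return float(np.mean(accs))


def select_atm_threshold(
    features_by_threshold: dict[float, np.ndarray],
    labels: np.ndarray,
    inner_splits: int = 3,
    rng_seed: int = 0,
) -> float:
    """Pick the binarization threshold maximizing inner-CV accuracy.

    ``features_by_threshold`` maps each candidate z threshold to the feature
    matrix of the *training* trials only (per-trial ATM features are
    trial-local, so precomputing them leaks nothing). Candidates whose
    features are all zero (no avalanches anywhere) are skipped with a
    warning; ties go to the smallest threshold.
    """
    if not features_by_threshold:
        raise ValueError("empty threshold grid")
    labels = np.asarray(labels)
    best_thr, best_acc = None, -np.inf
    for thr in sorted(features_by_threshold):
        feats = features_by_threshold[thr]
        if not np.any(feats):
            warnings.warn(f"threshold {thr}: no avalanches on training trials; skipped",
                          stacklevel=2)
            continue
        acc = _inner_cv_accuracy(feats, labels, inner_splits, rng_seed)
        if acc > best_acc:
            best_thr, best_acc = thr, acc
    if best_thr is None:
        raise ValueError("every candidate threshold yields empty avalanche sets")
    return best_thr


@dataclass
class DecodingResult:
    subject_id: str
    accuracies: dict[str, np.ndarray]  # pipeline -> per-split accuracy
    split_test_indices: list[np.ndarray]
    chosen_thresholds: np.ndarray
    n_splits: int
    test_fraction: float
    means: dict[str, float] = field(init=False)
    sds: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.means = {k: float(v.mean()) for k, v in self.accuracies.items()}
        # intra-subject variability: sd of accuracy across splits
        self.sds = {k: float(v.std(ddof=1)) for k, v in self.accuracies.items()}


def evaluate_pipelines(
    data: EpochedSourceData,
    n_splits: int = 50,
    test_fraction: float = 0.2,
    rng_seed: int = 0,
    csp_modes: int = 8,
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    bin_length_samples: int = 1,
    inner_splits: int = 3,
) -> DecodingResult:
    """Benchmark ATM+SVM against CSP+SVM on one subject.

    Stratified random 80/20 splits (seeded, identical for both pipelines);
    per split the CSP filters are fitted and the ATM threshold selected on
    the training trials only.
    """
    labels = np.asarray(data.condition_labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need >= 10 trials per class for a stable benchmark")
    signals = np.asarray(data.signals, dtype=float)

    # Per-trial ATM features for every candidate threshold (trial-local).
    feats_by_thr: dict[float, np.ndarray] = {}
    for thr in threshold_grid:
        atms = extract_trial_atms(data, threshold_z=thr, bin_length_samples=bin_length_samples)
        feats_by_thr[thr] = atm_features(atms.matrices, atms.has_avalanches)

    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=rng_seed
    )
    acc_atm = np.empty(n_splits)
    acc_csp = np.empty(n_splits)
    chosen = np.empty(n_splits)
    test_sets: list[np.ndarray] = []
    for k, (train, test) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        test_sets.append(test.copy())
        thr = select_atm_threshold(
            {t: f[train] for t, f in feats_by_thr.items()},
            labels[train],
            inner_splits=inner_splits,
            rng_seed=rng_seed + k,
        )
        chosen[k] = thr
        feats = feats_by_thr[thr]
        clf = _make_svm().fit(feats[train], labels[train])
        acc_atm[k] = clf.score(feats[test], labels[test])

        filters = csp_fit(signals[train], labels[train], n_modes=csp_modes)
        train_f = csp_features(signals[train], filters)
        test_f = csp_features(signals[test], filters)
        clf = _make_svm().fit(train_f, labels[train])
        acc_csp[k] = clf.score(test_f, labels[test])
    return DecodingResult(
        subject_id=data.subject_id,
        accuracies={"atm": acc_atm, "csp": acc_csp},
        split_test_indices=test_sets,
        chosen_thresholds=chosen,
        n_splits=n_splits,
        test_fraction=test_fraction,
    )


def compare_pipelines(results: list[DecodingResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject paired comparison of the two pipelines' split accuracies.

    Paired t-test (primary) confirmed by Wilcoxon signed-rank; BH across
    subjects on the t p-values; three-way decision with direction. Zero
    variance of the paired differences is flagged degenerate and decided by
    the mean-difference sign.
    """
    rows = []
    for res in results:
        a, c = res.accuracies["atm"], res.accuracies["csp"]
        if a.shape != c.shape:
            raise ValueError("pipelines must share split counts")
        diff = a - c
        degenerate = np.allclose(diff, diff[0])
        if degenerate:
            t_stat, t_p, w_p = np.nan, (1.0 if diff[0] == 0 else 0.0), np.nan
        else:
            t_stat, t_p = ttest_rel(a, c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, w_p = wilcoxon(a, c, zero_method="wilcox")
        rows.append(
            {
                "subject_id": res.subject_id,
                "atm_mean": res.means["atm"],
                "csp_mean": res.means["csp"],
                "atm_sd": res.sds["atm"],
                "csp_sd": res.sds["csp"],
                "mean_diff": float(diff.mean()),
                "t_stat": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "t_p": float(t_p),
                "wilcoxon_p": float(w_p) if np.isfinite(w_p) else np.nan,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    reject, _ = bh_correct(table["t_p"].to_numpy(), alpha)
    decisions = []
    for rej, diff in zip(reject, table["mean_diff"]):
        if not rej or diff == 0:
            decisions.append("no difference")
        else:
            decisions.append("ATM better" if diff > 0 else "CSP better")
    table["decision"] = decisions
    return table
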