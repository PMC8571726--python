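"""Behavioral read-out of the numerosity code: matching, categorization,
and unit-silencing ablations.

The *matching task* mirrors delayed match-to-numerosity experiments: on
each trial two dot displays are shown and a maximum-margin classifier
(linear SVM on the concatenated selective-unit response vectors of the two
displays) judges whether they contain the same number of items.  Test
trials are tabulated into *performance tuning functions* — the probability
of a "same" response as a function of the test numerosity for each sample
numerosity — whose widths express the behavioral distance and size
effects.

The *categorization task* trains a multi-class one-vs-one SVM to label
single displays with their numerosity from selective-unit activity,
yielding a confusion matrix and per-class true-positive rates.  Silencing
conditions zero out designated units' activity at classifier test time
only (training always sees intact activity), probing the causal
contribution of, e.g., the zero-tuned subpopulation to empty-set
judgments.

All operations act on activation features; any callable mapping an image
stack to feature vectors can serve as the recorder, so the same code runs
on the full network or on planted synthetic codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import tuning as _tuning
from .stimuli import SETS, generate_stimulus

__all__ = [
    "MatchingTrialSet",
    "MatchingResult",
    "PerformanceFunction",
    "ConfusionMatrix",
    "SilencingCondition",
    "CategorizationResult",
    "build_matching_trials",
    "train_test_matching",
    "matching_study",
    "performance_fits",
    "categorize_numerosity",
    "choose_silencing",
    "silencing_study",
]

MIN_REPS = 5  # minimum repetitions for the paired silencing test


# ---------------------------------------------------------------------------
# Matching task
# ---------------------------------------------------------------------------


@dataclass
class MatchingTrialSet:
    """Paired-display trials with the recorded feature vectors."""

    trials: pd.DataFrame  # sample_numerosity, test_numerosity, same (bool)
    sample_acts: np.ndarray  # (n_trials, n_features)
    test_acts: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return self.trials["same"].to_numpy()


def build_matching_trials(
    recorder: Callable[[np.ndarray], np.ndarray],
    n_trials: int,
    numerosities: Sequence[int] = (0, 1, 2, 3, 4),
    rng: np.random.Generator | None = None,
    sets: Sequence[str] = SETS,
    image_size: int = 224,
) -> MatchingTrialSet:
    """Freshly generated matching trials, balanced 50/50 same/different.

    ``recorder`` maps an image stack (B, H, W) to feature vectors
    (B, n_features) — typically the selective-unit responses of the
    network recorded with noise.  Restricting ``sets`` evaluates transfer
    to single control sets.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    numerosities = list(numerosities)
    if not numerosities:
        raise ValueError("empty numerosity range")
    rng = rng if rng is not None else np.random.default_rng()
    rows, images = [], []
    for t in range(n_trials):
        same = t < (n_trials + 1) // 2
        s = int(numerosities[rng.integers(len(numerosities))])
        if same or len(numerosities) == 1:
            q = s
        else:
            others = [n for n in numerosities if n != s]
            q = int(others[rng.integers(len(others))])
        for n in (s, q):
            set_id = sets[rng.integers(len(sets))]
            _, img = generate_stimulus(n, set_id, rng, image_size)
            images.append(img)
        rows.append(
            {"trial": t, "sample_numerosity": s, "test_numerosity": q,
             "same": s == q}
        )
    feats = recorder(np.stack(images))
    trials = pd.DataFrame(rows)
    # shuffle so class labels are not ordered
    order = rng.permutation(n_trials)
    return MatchingTrialSet(
        trials=trials.iloc[order].reset_index(drop=True),
        sample_acts=feats[0::2][order],
        test_acts=feats[1::2][order],
    )


@dataclass
class PerformanceFunction:
    """P("same") per test numerosity, for one sample numerosity."""

    sample_numerosity: int
    test_numerosities: np.ndarray
    p_same: np.ndarray
    sem: np.ndarray  # across repetitions (zeros for a single run)
    n_trials: np.ndarray = field(default=None)


@dataclass
class MatchingResult:
    accuracy: float
    accuracy_zero_trials: float
    performance: list[PerformanceFunction]
    predictions: pd.DataFrame
    p_same_matrix: np.ndarray  # (n_sample_nums, n_test_nums), NaN where unseen
    numerosities: np.ndarray


def train_test_matching(
    train: MatchingTrialSet,
    test: MatchingTrialSet,
    C: float = 1.0,
    kernel: str = "rbf",
) -> MatchingResult:
    """Train the maximum-margin matcher and evaluate it.

    Features are the concatenation sample‖test of the two displays' unit
    responses.  The same/different judgment is a similarity computation
    that is not linearly separable in that concatenation, so the default
    kernel is the radial basis function.  Reports overall test accuracy,
    accuracy restricted to trials involving numerosity 0, and the
    performance tuning functions.
    """
    y_train = train.labels
    if len(np.unique(y_train)) < 2:
        raise ValueError("training trials contain a single class")
    Xtr = np.hstack([train.sample_acts, train.test_acts])
    Xte = np.hstack([test.sample_acts, test.test_acts])
    clf = SVC(kernel=kernel, C=C)
    clf.fit(Xtr, y_train)
    pred = clf.predict(Xte)
    y_test = test.labels
    acc = float(np.mean(pred == y_test))
    t = test.trials.copy()
    t["predicted_same"] = pred
    t["correct"] = pred == y_test
    zero = (t["sample_numerosity"] == 0) | (t["test_numerosity"] == 0)
    acc_zero = float(t.loc[zero, "correct"].mean()) if zero.any() else float("nan")
    nums = np.unique(
        np.concatenate([t["sample_numerosity"], t["test_numerosity"]])
    )
    mat = np.full((len(nums), len(nums)), np.nan)
    cnt = np.zeros((len(nums), len(nums)), int)
    perf = []
    for i, s in enumerate(nums):
        ps, ns = [], []
        for j, q in enumerate(nums):
            sel = (t["sample_numerosity"] == s) & (t["test_numerosity"] == q)
            n = int(sel.sum())
            cnt[i, j] = n
            if n:
                mat[i, j] = float(t.loc[sel, "predicted_same"].mean())
            ps.append(mat[i, j])
            ns.append(n)
        perf.append(
            PerformanceFunction(
                sample_numerosity=int(s),
                test_numerosities=nums.copy(),
                p_same=np.asarray(ps, float),
                sem=np.zeros(len(nums)),
                n_trials=np.asarray(ns),
            )
        )
    return MatchingResult(
        accuracy=acc,
        accuracy_zero_trials=acc_zero,
        performance=perf,
        predictions=t,
        p_same_matrix=mat,
        numerosities=nums,
    )


@dataclass
class MatchingStudy:
    accuracy: float
    accuracy_se: float
    accuracy_zero: float
    accuracy_zero_se: float
    performance: list[PerformanceFunction]  # across-repetition mean ± s.e.
    per_rep: pd.DataFrame
    numerosities: np.ndarray
    results: list = field(default_factory=list)


def matching_study(
    recorder_factory: Callable[[int], Callable],
    n_reps: int = 50,
    n_train: int = 600,
    n_test: int = 600,
    numerosities: Sequence[int] = (0, 1, 2, 3, 4),
    sets: Sequence[str] = SETS,
    base_seed: int = 0,
    image_size: int = 224,
    C: float = 1.0,
) -> MatchingStudy:
    """Repeat data generation, matcher training and testing ``n_reps``
    times and aggregate accuracies and performance tuning functions.

    ``recorder_factory(seed)`` must return a fresh feature recorder for
    each repetition (e.g. one binding the network with a repetition-
    specific noise seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    rows, mats, results = [], [], []
    nums = None
    for rep, child in enumerate(ss.spawn(n_reps)):
        s_rec, s_tr, s_te = [
            int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3)
        ]
        recorder = recorder_factory(s_rec)
        train = build_matching_trials(
            recorder, n_train, numerosities, np.random.default_rng(s_tr),
            sets, image_size,
        )
        test = build_matching_trials(
            recorder, n_test, numerosities, np.random.default_rng(s_te),
            sets, image_size,
        )
        res = train_test_matching(train, test, C=C)
        results.append(res)
        nums = res.numerosities
        mats.append(res.p_same_matrix)
        rows.append(
            {"rep": rep, "accuracy": res.accuracy,
             "accuracy_zero": res.accuracy_zero_trials}
        )
    per_rep = pd.DataFrame(rows)
    stack = np.stack(mats)  # (reps, S, T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cells unseen in some repetitions
        mean = np.nanmean(stack, axis=0)
        n_ok = np.sum(np.isfinite(stack), axis=0)
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    perf = [
        PerformanceFunction(int(s), nums.copy(), mean[i], sem[i])
        for i, s in enumerate(nums)
    ]

    def _mse(col):
        v = per_rep[col].to_numpy()
        return float(np.mean(v)), (
            float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        )

    acc, acc_se = _mse("accuracy")
    accz, accz_se = _mse("accuracy_zero")
    return MatchingStudy(
        accuracy=acc,
        accuracy_se=acc_se,
        accuracy_zero=accz,
        accuracy_zero_se=accz_se,
        performance=perf,
        per_rep=per_rep,
        numerosities=nums,
        results=results,
    )


@dataclass
class PerformanceFitSummary:
    widths: dict  # sample numerosity -> fitted Gaussian width (log axis NaN-safe)
    size_effect_r: float
    size_effect_p: float
    scale: "_tuning.ScaleComparison | None"
    excluded: list


def performance_fits(
    performance: Sequence[PerformanceFunction],
    axis: str = "linear",
) -> PerformanceFitSummary:
    """Gaussian fits of the performance tuning functions.

    Returns per-sample-numerosity fitted widths, the Pearson correlation of
    width with sample numerosity (behavioral size effect), and — when at
    least five functions fit on both axes — the paired linear/log r²
    comparison.
    """
    if len(performance) < 3:
        raise ValueError("need performance functions for >= 3 sample numerosities")
    widths, prefs, excluded, curves = {}, [], [], []
    nums = performance[0].test_numerosities
    for pf in performance:
        y = pf.p_same
        ok = np.isfinite(y)
        if ok.sum() < 4 or np.nanmax(y) - np.nanmin(y) < 1e-12:
            excluded.append(pf.sample_numerosity)
            continue
        fit = _tuning.fit_gaussian(y[ok], nums[ok], axis=axis)
        if not fit.converged:
            excluded.append(pf.sample_numerosity)
            continue
        widths[pf.sample_numerosity] = fit.width_sd
        prefs.append(pf.sample_numerosity)
        curves.append(y[ok])
    if len(prefs) >= 3:
        r, p = stats.pearsonr(prefs, [widths[k] for k in prefs])
    else:
        r, p = float("nan"), float("nan")
    scale = None
    if len(curves) >= _tuning.MIN_PAIRS:
        try:
            scale = _tuning.scale_comparison(curves=curves, numerosities=nums)
        except ValueError:
            scale = None
    return PerformanceFitSummary(
        widths=widths, size_effect_r=float(r), size_effect_p=float(p),
        scale=scale, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Categorization and silencing
# ---------------------------------------------------------------------------


@dataclass
class SilencingCondition:
    mode: str  # none | zero_tuned | random_nonzero_matched | all_tuned_to_k
    unit_ids: np.ndarray  # feature-column indices silenced at test time
    k: int | None = None  # target numerosity for all_tuned_to_k


def choose_silencing(
    preferred: np.ndarray,
    mode: str,
    rng: np.random.Generator | None = None,
    k: int | None = None,
) -> SilencingCondition:
    """Pick the silenced unit set for a condition.

    ``preferred`` is the preferred numerosity of each feature column.
    ``random_nonzero_matched`` draws as many nonzero-tuned units as there
    are zero-tuned ones.
    """
    preferred = np.asarray(preferred)
    if mode == "none":
        ids = np.array([], int)
    elif mode == "zero_tuned":
        ids = np.flatnonzero(preferred == 0)
    elif mode == "random_nonzero_matched":
        n_zero = int(np.sum(preferred == 0))
        pool = np.flatnonzero(preferred != 0)
        if n_zero > len(pool):
            raise ValueError("not enough nonzero-tuned units to match")
        rng = rng if rng is not None else np.random.default_rng()
        ids = rng.choice(pool, size=n_zero, replace=False)
    elif mode == "all_tuned_to_k":
        if k is None:
            raise ValueError("all_tuned_to_k needs k")
        ids = np.flatnonzero(preferred == k)
    else:
        raise ValueError(f"unknown silencing mode {mode!r}")
    return SilencingCondition(mode=mode, unit_ids=np.sort(ids), k=k)


@dataclass
class ConfusionMatrix:
    classes: np.ndarray
    counts: np.ndarray  # (true, predicted)

    @property
    def rates(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return self.counts / sums

    @property
    def tpr(self) -> np.ndarray:
        """Per-class true-positive rate (diagonal of the row rates)."""
        return np.diag(self.rates)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class CategorizationResult:
    confusion: ConfusionMatrix
    accuracy: float
    tpr: np.ndarray
    error_confusion: ConfusionMatrix | None = None
    error_accuracy: float | None = None
    silencing: SilencingCondition | None = None


def _confusion(y_true, y_pred, classes) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes=np.asarray(classes), counts=counts)


def categorize_numerosity(
    acts: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator | None = None,
    silencing: SilencingCondition | None = None,
    error_acts: np.ndarray | None = None,
    error_labels: np.ndarray | None = None,
    C: float = 1.0,
) -> CategorizationResult:
    """Multi-class (one-vs-one SVM) numerosity categorization.

    Half of the images train the classifier (always with intact activity);
    the held-out half — and, when given, the error-trial images — are
    evaluated with the silencing condition applied (silenced units' test
    activity set to zero).
    """
    acts = np.asarray(acts, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 numerosity classes")
    if silencing is not None and len(silencing.unit_ids):
        if silencing.unit_ids.max() >= acts.shape[1]:
            raise ValueError("silencing ids are not a subset of the feature units")
    rng = rng if rng is not None else np.random.default_rng()
    order = rng.permutation(len(labels))
    half = len(labels) // 2
    tr, te = order[:half], order[half:]
    if len(np.unique(labels[tr])) < 2:
        raise ValueError("training half contains fewer than 2 classes")
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(acts[tr], labels[tr])

    def _silence(X):
        if silencing is None or not len(silencing.unit_ids):
            return X
        X = X.copy()
        X[:, silencing.unit_ids] = 0.0
        return X

    pred = clf.predict(_silence(acts[te]))
    cm = _confusion(labels[te], pred, classes)
    err_cm, err_acc = None, None
    if error_acts is not None and len(error_acts):
        epred = clf.predict(_silence(np.asarray(error_acts, float)))
        err_cm = _confusion(np.asarray(error_labels), epred, classes)
        err_acc = err_cm.accuracy
    return CategorizationResult(
        confusion=cm,
        accuracy=cm.accuracy,
        tpr=cm.tpr,
        error_confusion=err_cm,
        error_accuracy=err_acc,
        silencing=silencing,
    )


@dataclass
class SilencingStudy:
    conditions: list[str]
    tpr: dict  # condition -> (n_reps, n_classes) true-positive rates
    zero_tpr_mean: dict  # condition -> mean zero-class TPR
    tests: dict  # (cond_a, cond_b) -> (stat, p) paired Wilcoxon on zero TPR
    classes: np.ndarray


def silencing_study(
    acts: np.ndarray,
    labels: np.ndarray,
    preferred: np.ndarray,
    modes: Sequence[str] = ("none", "zero_tuned", "random_nonzero_matched"),
    ks: Sequence[int] = (),
    n_reps: int = 10,
    base_seed: int = 0,
    C: float = 1.0,
) -> SilencingStudy:
    """Categorization under silencing conditions, repeated over random
    train/test splits, with paired Wilcoxon tests of the zero-class
    true-positive rate against the intact condition.

    ``preferred`` gives each feature column's preferred numerosity; per-k
    conditions from ``ks`` are labelled ``"class:k"``.
    """
    if n_reps < MIN_REPS:
        raise ValueError(f"need >= {MIN_REPS} repetitions for the paired test")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    conds = list(modes) + [f"class:{k}" for k in ks]
    tprs: dict = {c: [] for c in conds}
    ss = np.random.SeedSequence(base_seed)
    for rep, child in enumerate(ss.spawn(n_reps)):
        split_seed, sil_seed = [
            int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2)
        ]
        for cond in conds:
            if cond.startswith("class:"):
                sil = choose_silencing(
                    preferred, "all_tuned_to_k", k=int(cond.split(":")[1])
                )
            else:
                sil = choose_silencing(
                    preferred, cond, rng=np.random.default_rng(sil_seed)
                )
            res = categorize_numerosity(
                acts, labels, rng=np.random.default_rng(split_seed),
                silencing=sil, C=C,
            )
            tprs[cond].append(res.tpr)
    tpr = {c: np.stack(v) for c, v in tprs.items()}
    zero_col = int(np.flatnonzero(classes == 0)[0]) if 0 in classes else 0
    tests = {}
    for cond in conds:
        if cond == "none":
            continue
        a = tpr["none"][:, zero_col]
        b = tpr[cond][:, zero_col]
        tests[("none", cond)] = _tuning._wilcoxon(a, b)
    return SilencingStudy(
        conditions=conds,
        tpr=tpr,
        zero_tpr_mean={c: float(v[:, zero_col].mean()) for c, v in tpr.items()},
        tests=tests,
        classes=classes,
    )
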