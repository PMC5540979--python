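"""Metrics, ROC/AUC, cross-validation, paired t-tests, and experiment sweeps.

The positive class throughout is the *normal* state (+1); fatigue is
the negative class (-1).  ``TP`` therefore counts correctly identified
normal units and ``TN`` correctly identified fatigue units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .entropy import feature_columns
from .recording import state_to_sign

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion",
    "binary_metrics",
    "roc_curve_auc",
    "kfold_split",
    "cross_validate",
    "paired_t_test",
    "sweep_max_depth",
    "sweep_learning_rate",
    "sweep_test_ratio",
    "sweep_n_subjects",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """The five scalar metrics, with flags naming degenerate denominators."""

    err: float
    precision: float
    recall: float
    f1: float
    mcc: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "err": self.err,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


@dataclass
class EvalReport:
    """Aggregate of a cross-validated evaluation.

    Scalar fields are means over runs; ``std`` holds the matching
    standard deviations, ``per_run`` the individual run summaries, and
    ``roc`` the vertically averaged ROC curve as (fpr, tpr) arrays.
    """

    err: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float
    std: dict[str, float] = field(default_factory=dict)
    roc: tuple[np.ndarray, np.ndarray] | None = None
    per_run: list[dict] = field(default_factory=list)
    n_runs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "err": self.err,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts for labels in {-1, +1} with +1 = normal = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def binary_metrics(c: ConfusionCounts) -> Metrics:
    """ERR, Precision, Recall, F1 and MCC from confusion counts.

    Degenerate denominators (e.g. no predicted positives) yield 0 for
    the affected metric, with the metric named in ``degenerate``.
    """
    if c.total <= 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    err = (c.fp + c.fn) / c.total

    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, flags = 0.0, flags + ["recall"]
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, flags = 0.0, flags + ["f1"]

    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    else:
        mcc, flags = 0.0, flags + ["mcc"]
    return Metrics(err, precision, recall, f1, float(mcc), tuple(flags))


def roc_curve_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC from continuous scores.

    Thresholds sweep the unique score values from high to low; tied
    scores move as one step (so the curve travels diagonally through
    ties, matching the Mann-Whitney convention of counting ties as
    one half).  Returns ``(fpr, tpr, auc)`` with the curve anchored at
    (0, 0) and (1, 1) and fpr non-decreasing.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = (y_true[order] == 1).astype(float)
    # indices where a new distinct score starts the next group
    distinct = np.nonzero(np.diff(s))[0]
    cum_tp = np.cumsum(pos)
    cum_fp = np.cumsum(1.0 - pos)
    tp = np.concatenate(([0.0], cum_tp[distinct], [cum_tp[-1]]))
    fp = np.concatenate(([0.0], cum_fp[distinct], [cum_fp[-1]]))
    fpr = fp / n_neg
    tpr = tp / n_pos
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def kfold_split(
    n_units: int,
    k: int,
    seed: int,
    stratify: np.ndarray | None = None,
) -> np.ndarray:
    """Shuffled (optionally stratified) fold assignment of ``n_units`` ids.

    Returns an array mapping each unit to a fold in ``0..k-1``; fold
    sizes differ by at most one, and with ``stratify`` the class ratio
    per fold is preserved to within one unit.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_units:
        raise ValueError(f"k={k} exceeds the number of units {n_units}")
    folds = np.empty(n_units, dtype=int)
    if stratify is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n_units), np.asarray(stratify))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n_units))
    for fold_idx, (_, test_idx) in enumerate(split_iter):
        folds[test_idx] = fold_idx
    return folds


def _table_xy(table: pd.DataFrame, feature_cols=None):
    cols = feature_cols or feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = np.array([state_to_sign(s) for s in table["state"]])
    return X, y


def _run_seed(seed: int, run: int) -> int:
    return int((seed * 100003 + run * 7919 + 17) % (2**31 - 1))


_FPR_GRID = np.linspace(0.0, 1.0, 101)


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    """Step-consistent interpolation of one ROC onto the common FPR grid."""
    # keep the highest tpr at each distinct fpr so np.interp is well defined
    df = pd.DataFrame({"fpr": fpr, "tpr": tpr}).groupby("fpr", sort=True).max()
    return np.interp(_FPR_GRID, df.index.to_numpy(), df["tpr"].to_numpy())


def cross_validate(
    table: pd.DataFrame,
    classifier,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of a classifier on a feature table.

    Each of the ``n_runs`` runs re-randomizes the fold assignment with
    a distinct seed derived from ``seed``; within a run every unit is
    scored exactly once (in its test fold).  Run metrics are computed
    on the pooled out-of-fold predictions; the report carries means and
    SDs over runs, the per-run summaries, and a mean ROC obtained by
    vertical averaging on a fixed FPR grid.
    """
    X, y = _table_xy(table, feature_cols)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes in the table")

    per_run: list[dict] = []
    tpr_curves = []
    for run in range(n_runs):
        folds = kfold_split(len(y), k, _run_seed(seed, run), stratify=y)
        preds = np.empty(len(y), dtype=int)
        scores = np.empty(len(y), dtype=float)
        for fold in range(k):
            test = folds == fold
            model = clone(classifier).fit(X[~test], y[~test])
            scores[test] = model.decision_function(X[test])
            preds[test] = model.predict(X[test])
        m = binary_metrics(confusion(y, preds))
        fpr, tpr, auc = roc_curve_auc(y, scores)
        summary = m.as_dict() | {"auc": auc}
        per_run.append(summary)
        tpr_curves.append(_interp_roc(fpr, tpr))

    keys = ["err", "precision", "recall", "f1", "mcc", "auc"]
    means = {key: float(np.mean([r[key] for r in per_run])) for key in keys}
    stds = {key: float(np.std([r[key] for r in per_run], ddof=1) if n_runs > 1 else 0.0)
            for key in keys}
    mean_tpr = np.mean(tpr_curves, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return EvalReport(
        **means, std=stds, roc=(_FPR_GRID.copy(), mean_tpr),
        per_run=per_run, n_runs=n_runs,
    )


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-run measurements.

    Degenerate cases: identical vectors give ``(0, 1)``; a constant
    nonzero difference (zero variance) gives an infinite statistic and
    ``p = 0`` as a sentinel.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def plot_roc(report: EvalReport, path, label: str = "classifier") -> None:
    """Render the report's mean ROC curve to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr = report.roc
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"{label} (AUC={report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- experiment sweeps ------------------------------------------------------

def sweep_max_depth(
    table: pd.DataFrame,
    depths: list[int],
    lr: float = 1.0,
    M: int = 500,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-validated ERR of the boosted ensemble per tree depth."""
    from .boosting import AdaBoostBinaryClassifier

    if not depths:
        raise ValueError("empty depth list")
    rows = []
    for depth in depths:
        clf = AdaBoostBinaryClassifier(
            n_estimators=M, learning_rate=lr, max_depth=depth
        )
        report = cross_validate(table, clf, k=k, n_runs=n_runs, seed=seed)
        rows.append({"max_depth": depth, "mean_err": report.err,
                     "sd_err": report.std["err"]})
    return pd.DataFrame(rows)


def sweep_learning_rate(
    table: pd.DataFrame,
    lrs: list[float],
    max_depth: int = 9,
    M: int = 500,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-validated ERR of the boosted ensemble per learning rate."""
    from .boosting import AdaBoostBinaryClassifier

    if not lrs:
        raise ValueError("empty learning-rate list")
    rows = []
    for lr in lrs:
        clf = AdaBoostBinaryClassifier(
            n_estimators=M, learning_rate=lr, max_depth=max_depth
        )
        report = cross_validate(table, clf, k=k, n_runs=n_runs, seed=seed)
        rows.append({"lr": lr, "mean_err": report.err, "sd_err": report.std["err"]})
    return pd.DataFrame(rows)


def sweep_test_ratio(
    table: pd.DataFrame,
    ratios: list[float],
    classifiers: dict,
    n_repeats: int = 10,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Mean single-split ERR per classifier as the test fraction varies.

    For each ratio the units are split at random (stratified by class)
    into train and test; ratios that leave either side empty are
    skipped with a warning.
    """
    import warnings

    X, y = _table_xy(table, feature_cols)
    rows = []
    for ratio in ratios:
        if not 0 < ratio < 1:
            raise ValueError(f"test ratio {ratio} outside (0, 1)")
        n_test = int(round(ratio * len(y)))
        if n_test < 2 or len(y) - n_test < 2:
            warnings.warn(f"ratio {ratio} leaves too few units; skipped",
                          stacklevel=2)
            continue
        for name, clf in classifiers.items():
            errs = []
            for rep in range(n_repeats):
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X, y, test_size=ratio, stratify=y,
                    random_state=_run_seed(seed, rep),
                )
                model = clone(clf).fit(X_tr, y_tr)
                errs.append(binary_metrics(confusion(y_te, model.predict(X_te))).err)
            rows.append({"ratio": ratio, "classifier": name,
                         "mean_err": float(np.mean(errs)),
                         "sd_err": float(np.std(errs, ddof=1) if n_repeats > 1 else 0.0)})
    return pd.DataFrame(rows)


def sweep_n_subjects(
    table: pd.DataFrame,
    n_values: list[int],
    classifiers: dict,
    repeats: int = 20,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-validated ERR per classifier as the cohort size varies.

    For each ``n`` a random subset of ``n`` subjects is drawn (without
    replacement) ``repeats`` times; the pooled units of each subset are
    evaluated by a single k-fold cross-validation run.
    """
    subjects = np.asarray(sorted(table["subject"].unique()))
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        if n > subjects.size:
            raise ValueError(f"n={n} exceeds the cohort of {subjects.size} subjects")
        errs: dict[str, list[float]] = {name: [] for name in classifiers}
        for rep in range(repeats):
            subset = rng.choice(subjects, size=n, replace=False)
            sub = table[table["subject"].isin(subset)].reset_index(drop=True)
            for name, clf in classifiers.items():
                report = cross_validate(
                    sub, clf, k=k, n_runs=1, seed=_run_seed(seed, rep)
                )
                errs[name].append(report.err)
        for name in classifiers:
            e = errs[name]
            rows.append({"n_subjects": n, "classifier": name,
                         "mean_err": float(np.mean(e)),
                         "sd_err": float(np.std(e, ddof=1) if repeats > 1 else 0.0)})
    return pd.DataFrame(rows)
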