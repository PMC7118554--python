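"""Performance estimation: repeated stratified k-fold CV, LOOCV, hold-out.

Labels follow the +1 (patient) / -1 (control) convention: sensitivity is
computed on the +1 class, specificity on -1.  ROC scores are SVM decision
values (no probability calibration layer).  Within one CV round, test
predictions of all k folds are pooled into a single confusion matrix and a
single AUC; the report then averages across rounds ("the final average
performance after all rounds").

Metrics are held internally as fractions in [0, 1]; rendering as percent is
left to the callers/reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.svm import SVC

__all__ = [
    "EvaluationReport",
    "HoldoutReport",
    "roc_auc",
    "repeated_kfold",
    "loocv",
    "holdout_protocol",
]


@dataclass
class EvaluationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    protocol: str  # e.g. "kfold10x100", "loocv", "holdout-test"
    feature_set: str = ""
    round_metrics: dict[str, np.ndarray] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def as_percent(self) -> dict[str, float]:
        """Confusion metrics in percent, AUC as a fraction (table layout)."""
        return {
            "sensitivity_pct": 100 * self.sensitivity,
            "specificity_pct": 100 * self.specificity,
            "accuracy_pct": 100 * self.accuracy,
            "auc": self.auc,
        }


@dataclass
class HoldoutReport:
    train: EvaluationReport
    test: EvaluationReport
    selected: np.ndarray
    params: "KernelParams"  # noqa: F821
    n_train: int
    n_test: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR, threshold) and trapezoidal AUC.

    The trapezoidal area over the full ROC equals the Mann-Whitney
    probability that a random patient scores above a random control, with
    tied scores counted 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute ROC/AUC")
    fpr, tpr, thr = roc_curve(y, s, pos_label=+1, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr, thr]), auc


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity on +1, specificity on -1, accuracy); NaN for empty cells."""
    pos = y_true == +1
    neg = y_true == -1
    sens = float((y_pred[pos] == +1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == -1).mean()) if neg.any() else np.nan
    acc = float((y_pred == y_true).mean())
    return sens, spec, acc


class _DegenerateModel:
    """Stand-in for SVC when a training fold contains a single class: it
    predicts that lone class with decision value equal to the class sign."""

    def __init__(self, label: int):
        self.label = int(label)

    def predict(self, x):
        return np.full(len(x), self.label)

    def decision_function(self, x):
        return np.full(len(x), float(self.label))


def _fit(x: np.ndarray, y: np.ndarray, params) -> object:
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training fold; using degenerate constant model")
        return _DegenerateModel(y[0])
    model = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    model.fit(x, y)
    return model


def repeated_kfold(
    features: np.ndarray,
    labels: np.ndarray,
    params,
    k: int = 10,
    rounds: int = 100,
    seed: int = 0,
    stratified: bool = True,
    feature_set: str = "",
) -> EvaluationReport:
    """Repeated (shuffled) k-fold CV; per-round pooled metrics, then averaged."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if stratified and k > min((y == +1).sum(), (y == -1).sum()):
        raise ValueError("k exceeds the smaller group size under stratification")
    per_round = {m: np.empty(rounds) for m in ("sensitivity", "specificity",
                                               "accuracy", "auc")}
    all_scores, all_labels = [], []
    for r in range(rounds):
        cv_cls = StratifiedKFold if stratified else KFold
        cv = cv_cls(n_splits=k, shuffle=True, random_state=seed + r)
        pred = np.empty(len(y), dtype=int)
        score = np.empty(len(y))
        for tr, te in cv.split(x, y):
            model = _fit(x[tr], y[tr], params)
            pred[te] = model.predict(x[te])
            score[te] = model.decision_function(x[te])
        sens, spec, acc = _confusion(y, pred)
        _, auc = roc_auc(score, y)
        per_round["sensitivity"][r] = sens
        per_round["specificity"][r] = spec
        per_round["accuracy"][r] = acc
        per_round["auc"][r] = auc
        all_scores.append(score)
        all_labels.append(y)
    roc_pts, _ = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    return EvaluationReport(
        sensitivity=float(np.nanmean(per_round["sensitivity"])),
        specificity=float(np.nanmean(per_round["specificity"])),
        accuracy=float(np.mean(per_round["accuracy"])),
        auc=float(np.mean(per_round["auc"])),
        protocol=f"kfold{k}x{rounds}",
        feature_set=feature_set,
        round_metrics=per_round,
        sd={m: float(np.nanstd(v, ddof=1)) if rounds > 1 else 0.0
            for m, v in per_round.items()},
        roc_points=roc_pts,
    )


def loocv(features: np.ndarray, labels: np.ndarray, params,
          feature_set: str = "") -> EvaluationReport:
    """Leave-one-subject-out CV; deterministic given the data.

    With n=2 (one subject per class) every training fold is single-class
    and the degenerate constant model applies — each left-out subject is
    assigned the opposite class.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    pred = np.empty(len(y), dtype=int)
    score = np.empty(len(y))
    for i in range(len(y)):
        tr = np.r_[0:i, i + 1:len(y)]
        model = _fit(x[tr], y[tr], params)
        pred[i] = model.predict(x[i:i + 1])[0]
        score[i] = model.decision_function(x[i:i + 1])[0]
    sens, spec, acc = _confusion(y, pred)
    roc_pts, auc = roc_auc(score, y)
    return EvaluationReport(sensitivity=sens, specificity=spec, accuracy=acc,
                            auc=auc, protocol="loocv", feature_set=feature_set,
                            roc_points=roc_pts)


def holdout_protocol(
    features: np.ndarray,
    labels: np.ndarray,
    covariates: np.ndarray,
    split_fraction: float | int = 0.2,
    seed: int = 0,
    params=None,
    alpha: float = 0.001,
    screen_scope: str = "train_only",
    elimination_fraction: float = 0.1,
    n_max: int | None = None,
    inner_folds: int = 10,
    train_cv_k: int = 10,
    train_cv_rounds: int = 10,
    feature_set: str = "",
) -> HoldoutReport:
    """Stratified hold-out: fit the whole pipeline on ~(1-split) of subjects,
    freeze it, apply once to the rest.  ``split_fraction`` may be a fraction
    or an absolute test-set size (e.g. 26 of 99 subjects for the 73/26
    protocol).

    Selection (covariate fit, screening, RFE, subset choice) sees the
    training split ONLY; a structural guard verifies the index sets are
    disjoint before the frozen pipeline touches the test split.  The
    train-side CV estimate depends on ``screen_scope``:

    - ``'full'``: screening/RFE run once on the whole training split, and
      the k-fold CV is computed on the already-selected columns — the
      classical protocol, optimistically biased because selection saw the
      CV test folds.
    - ``'train_only'``: screening is refit inside each CV training fold
      (leakage-free screening estimate); RFE is applied only in the final
      frozen model.

    Either way the held-out test metrics are honest.
    """
    from .rfe import KernelParams, grid_search, rank_features, select_optimal_subset
    from .screening import regress_covariates, ttest_screen

    if screen_scope not in {"full", "train_only"}:
        raise ValueError(f"unknown screen_scope {screen_scope!r}")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    cov = np.asarray(covariates, dtype=float)
    idx = np.arange(len(y))
    tr_idx, te_idx = train_test_split(
        idx, test_size=split_fraction, stratify=y, random_state=seed
    )
    if np.intersect1d(tr_idx, te_idx).size:
        raise RuntimeError("leakage guard: train/test index sets overlap")
    for part, name in ((tr_idx, "training"), (te_idx, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} split does not contain both classes")

    # --- selection on the training split only ---
    x_tr_adj, adjuster = regress_covariates(x[tr_idx], cov[tr_idx])
    screen = ttest_screen(x_tr_adj, y[tr_idx], alpha=alpha)
    if screen.retained.size < 2:
        raise RuntimeError("fewer than 2 features survive screening on the "
                           "training split; lower alpha or enlarge the cohort")
    x_scr = x_tr_adj[:, screen.retained]
    if params is None:
        params = grid_search(x_scr, y[tr_idx], seed=seed)
    ranked = rank_features(x_scr, y[tr_idx], params, elimination_fraction)
    ranked = select_optimal_subset(ranked, x_scr, y[tr_idx], params,
                                   n_max=n_max, folds=inner_folds, seed=seed)
    selected = screen.retained[ranked.selected]

    # --- train-side CV estimate ---
    if screen_scope == "full":
        train_report = repeated_kfold(
            x_tr_adj[:, selected], y[tr_idx], params,
            k=train_cv_k, rounds=train_cv_rounds, seed=seed,
            feature_set=feature_set,
        )
    else:
        train_report = _screened_kfold(
            x[tr_idx], y[tr_idx], cov[tr_idx], params, alpha,
            k=train_cv_k, rounds=train_cv_rounds, seed=seed,
            feature_set=feature_set,
        )
    train_report.protocol = f"holdout-train-cv[{screen_scope}]"

    # --- frozen pipeline applied once to the held-out split ---
    model = _fit(x_tr_adj[:, selected], y[tr_idx], params)
    x_te_adj = adjuster.apply(x[te_idx], cov[te_idx])
    pred = model.predict(x_te_adj[:, selected])
    score = model.decision_function(x_te_adj[:, selected])
    sens, spec, acc = _confusion(y[te_idx], pred)
    roc_pts, auc = roc_auc(score, y[te_idx])
    test_report = EvaluationReport(
        sensitivity=sens, specificity=spec, accuracy=acc, auc=auc,
        protocol="holdout-test", feature_set=feature_set, roc_points=roc_pts,
    )
    return HoldoutReport(train=train_report, test=test_report,
                         selected=selected, params=params,
                         n_train=len(tr_idx), n_test=len(te_idx))


def _screened_kfold(
    x: np.ndarray, y: np.ndarray, cov: np.ndarray, params, alpha: float,
    k: int, rounds: int, seed: int, feature_set: str,
) -> EvaluationReport:
    """k-fold CV with covariate fit + screening refit inside every fold."""
    from .screening import regress_covariates, ttest_screen

    per_round = {m: np.empty(rounds) for m in ("sensitivity", "specificity",
                                               "accuracy", "auc")}
    all_scores, all_labels = [], []
    for r in range(rounds):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        pred = np.empty(len(y), dtype=int)
        score = np.empty(len(y))
        for tr, te in cv.split(x, y):
            x_tr, adjuster = regress_covariates(x[tr], cov[tr])
            scr = ttest_screen(x_tr, y[tr], alpha=alpha)
            cols = scr.retained
            if cols.size == 0:  # nothing survives: fall back to all columns
                cols = np.arange(x.shape[1])
            model = _fit(x_tr[:, cols], y[tr], params)
            x_te = adjuster.apply(x[te], cov[te])
            pred[te] = model.predict(x_te[:, cols])
            score[te] = model.decision_function(x_te[:, cols])
        sens, spec, acc = _confusion(y, pred)
        _, auc = roc_auc(score, y)
        for m, v in zip(("sensitivity", "specificity", "accuracy", "auc"),
                        (sens, spec, acc, auc)):
            per_round[m][r] = v
        all_scores.append(score)
        all_labels.append(y)
    roc_pts, _ = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    return EvaluationReport(
        sensitivity=float(np.nanmean(per_round["sensitivity"])),
        specificity=float(np.nanmean(per_round["specificity"])),
        accuracy=float(np.mean(per_round["accuracy"])),
        auc=float(np.mean(per_round["auc"])),
        protocol=f"screened-kfold{k}x{rounds}",
        feature_set=feature_set,
        round_metrics=per_round,
        sd={m: float(np.nanstd(v, ddof=1)) if rounds > 1 else 0.0
            for m, v in per_round.items()},
        roc_points=roc_pts,
    )
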