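"""Nonlinear (RBF-kernel) SVM recursive feature elimination.

The ranking criterion is the kernel-space margin sensitivity of Guyon-style
RFE: after training a soft-margin SVM with kernel K, the contribution of a
surviving feature f is

    dJ(f) = 1/2 a' H a  -  1/2 a' H(-f) a,

where a_i = alpha_i y_i over the support vectors, H = K(sv, sv) and H(-f)
is the same kernel recomputed with feature f removed, holding the dual
coefficients fixed.  For the RBF kernel K = exp(-gamma * ||x - x'||^2) the
leave-one-feature-out kernel factorizes,

    K(-f) = K * exp(gamma * (x_f - x'_f)^2),

so all dJ values at one iteration cost a single squared-difference matrix
per feature.  The feature(s) with smallest dJ are eliminated each round —
by default 10% of the survivors per round until 100 remain, then one at a
time — and the reverse elimination order is the importance ranking.

The optimal subset size is picked by cross-validated ROC AUC as a function
of the number of top-ranked features; the argmax (ties -> smallest n)
defines the selected subset, whose reporting weights are the rank positions
rescaled linearly onto [1, 0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import roc_auc

__all__ = ["KernelParams", "RFEResult", "grid_search", "rank_features",
           "select_optimal_subset", "svm_rfe"]

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))


@dataclass(frozen=True)
class KernelParams:
    """RBF-kernel SVM hyperparameters (libsvm's -c and -g)."""

    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class RFEResult:
    """Elimination-order ranking and AUC-based subset selection.

    ``ranking`` lists feature columns best-first (the reverse of
    ``elimination_order``); ``auc_curve[n-1]`` is the CV AUC of the top-n
    subset; ``weights`` rescales the selected subset's rank positions
    linearly to [1, 0] (best = 1.00, worst = 0.00).
    """

    elimination_order: np.ndarray
    ranking: np.ndarray
    auc_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    optimal_n: int | None = None
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> KernelParams:
    """Pick (C, gamma) maximizing mean stratified-CV accuracy.

    Ties broken toward the smallest C, then the smallest gamma.
    """
    if not c_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    _check_two_classes(labels)
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(x, y))
    best, best_acc = None, -np.inf
    for c in sorted(c_grid):
        for g in sorted(gamma_grid):
            correct = total = 0
            for tr, te in splits:
                model = SVC(C=c, gamma=g, kernel="rbf")
                model.fit(x[tr], y[tr])
                correct += int((model.predict(x[te]) == y[te]).sum())
                total += len(te)
            acc = correct / total
            if acc > best_acc + 1e-12:
                best, best_acc = KernelParams(C=c, gamma=g), acc
    return best


def _delta_j(sv: np.ndarray, a: np.ndarray, gamma: float) -> np.ndarray:
    """dJ for every feature of the current support-vector matrix.

    a = dual_coef (alpha_i * y_i).  dJ(f) = 1/2 a'(K - K(-f))a with
    K(-f) = K * exp(gamma * D_f), D_f the squared differences on feature f.
    """
    k = rbf_kernel(sv, sv, gamma=gamma)
    n_feat = sv.shape[1]
    dj = np.empty(n_feat)
    base = a @ k
    j_full = 0.5 * float(base @ a)
    for f in range(n_feat):
        d = sv[:, f, None] - sv[None, :, f]
        k_minus = k * np.exp(gamma * d * d)
        dj[f] = j_full - 0.5 * float(a @ k_minus @ a)
    return dj


def rank_features(
    features: np.ndarray,
    labels: np.ndarray,
    params: KernelParams,
    elimination_fraction: float = 0.1,
    single_step_below: int = 100,
) -> RFEResult:
    """Recursive elimination ranking of all feature columns.

    While more than ``single_step_below`` features survive, each round
    eliminates ``max(1, floor(fraction * survivors))`` features with the
    smallest dJ; after that, one per round.  Ties in dJ are broken toward
    the lower column index (eliminated first).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")

    surviving = np.arange(x.shape[1])
    eliminated: list[int] = []
    iteration = 0
    while surviving.size > 1:
        iteration += 1
        try:
            model = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
            model.fit(x[:, surviving], y)
        except Exception as exc:  # pragma: no cover - solver failure surface
            raise RuntimeError(f"SVM training failed at RFE iteration {iteration}") from exc
        sv = model.support_vectors_
        a = model.dual_coef_.ravel()
        dj = _delta_j(sv, a, params.gamma)

        if surviving.size > single_step_below:
            n_drop = max(1, int(elimination_fraction * surviving.size))
            n_drop = min(n_drop, surviving.size - 1)
        else:
            n_drop = 1
        # sort by (dJ, column index): equal dJ -> lower column goes first
        order = np.lexsort((surviving, dj))
        drop = order[:n_drop]
        eliminated.extend(surviving[drop].tolist())
        surviving = np.delete(surviving, drop)
    eliminated.append(int(surviving[0]))

    elimination_order = np.asarray(eliminated, dtype=int)
    return RFEResult(
        elimination_order=elimination_order,
        ranking=elimination_order[::-1].copy(),
    )


def _cv_scores(
    x: np.ndarray, y: np.ndarray, params: KernelParams, folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold decision values from a seeded stratified k-fold."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in cv.split(x, y):
        model = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        model.fit(x[tr], y[tr])
        scores[te] = model.decision_function(x[te])
    return scores


def select_optimal_subset(
    result: RFEResult,
    features: np.ndarray,
    labels: np.ndarray,
    params: KernelParams,
    n_max: int | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RFEResult:
    """Evaluate CV AUC of the top-n subsets and pick the argmax.

    The same seeded fold assignment is reused for every n so curve points
    differ only in the feature subset.  Ties in AUC go to the smallest n.
    Reporting weights for the selected subset are rank positions rescaled
    linearly to [1, 0].
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    ranking = result.ranking
    n_max = len(ranking) if n_max is None else min(n_max, len(ranking))
    curve = np.empty(n_max)
    for n in range(1, n_max + 1):
        scores = _cv_scores(x[:, ranking[:n]], y, params, folds, seed)
        _, curve[n - 1] = roc_auc(scores, y)
    optimal_n = int(np.argmax(curve)) + 1  # argmax returns first (smallest n) max
    selected = ranking[:optimal_n].copy()
    if optimal_n == 1:
        weights = np.array([1.0])
    else:
        weights = np.linspace(1.0, 0.0, optimal_n)
    result.auc_curve = curve
    result.optimal_n = optimal_n
    result.selected = selected
    result.weights = weights
    return result


def svm_rfe(
    features: np.ndarray,
    labels: np.ndarray,
    params: KernelParams,
    elimination_fraction: float = 0.1,
    n_max: int | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RFEResult:
    """rank_features followed by select_optimal_subset."""
    result = rank_features(features, labels, params, elimination_fraction)
    return select_optimal_subset(result, features, labels, params, n_max, folds, seed)
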