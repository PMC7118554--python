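"""Covariate adjustment and univariate feature screening.

Before any multivariate selection, each connectivity feature is replaced by
the residual of a least-squares fit on intercept + covariates (gender,
education), and a two-sample t-test then screens the adjusted features at
an uncorrected threshold (default p < 0.001).

The t-test uses the pooled-variance (Student) form by default — the common
default of clinical statistics packages — with Welch available by flag.
Screening can be run on all subjects at once (``scope='full'``, the
classical protocol, which is optimistic when followed by cross-validation
on the same subjects) or inside each training split only
(``scope='train_only'``, leakage-free); the screening functions themselves
are scope-agnostic — the evaluation protocols decide which subjects they
see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ScreenResult", "CovariateAdjuster", "regress_covariates", "ttest_screen"]


@dataclass
class ScreenResult:
    retained: np.ndarray  # sorted column indices with p < threshold
    t_statistic: np.ndarray  # per-column t
    p_value: np.ndarray  # per-column two-sided p
    threshold: float


@dataclass
class CovariateAdjuster:
    """Fitted covariate adjustment, applicable to held-out subjects.

    Stores the training-sample covariate means used for centering, the
    retained (non-constant) covariate columns, and the least-squares
    coefficients, so test subjects are adjusted by the training fit rather
    than refit (which would leak).
    """

    means: np.ndarray
    keep: np.ndarray
    beta: np.ndarray  # (1 + len(keep), n_features)

    def apply(self, features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        design = np.column_stack(
            [np.ones(c.shape[0]), (c - self.means)[:, self.keep]]
        )
        return np.asarray(features, dtype=float) - design @ self.beta


def regress_covariates(
    features: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, CovariateAdjuster]:
    """Residualize every feature column on intercept + covariates.

    Constant covariate columns (zero variance after centering) carry no
    information beyond the intercept and are dropped rather than making the
    design singular; with all covariates constant the features are simply
    centered.  Raises on a genuinely rank-deficient (collinear) design.
    Returns (residuals, fitted adjuster); residual columns are orthogonal
    to each covariate column and to the intercept.
    """
    x = np.asarray(features, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    means = c.mean(axis=0)
    centered = c - means
    keep = np.flatnonzero(np.ptp(centered, axis=0) > 0)
    design = np.column_stack([np.ones(c.shape[0]), centered[:, keep]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design: collinear columns among {keep.tolist()}"
        )
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    adjuster = CovariateAdjuster(means=means, keep=keep, beta=beta)
    return x - design @ beta, adjuster


def ttest_screen(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.001,
    welch: bool = False,
) -> ScreenResult:
    """Two-sample t-test per feature column; retain columns with p < alpha.

    Labels are +1 (patients) vs -1 (controls).  Degenerate columns with zero
    pooled variance get t = 0, p = 1 and are never retained.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = np.asarray(labels)
    x = np.asarray(features, dtype=float)
    a, b = x[labels == +1], x[labels == -1]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    retained = np.flatnonzero(p < alpha)
    return ScreenResult(retained=retained, t_statistic=t, p_value=p, threshold=alpha)
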