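"""Large-scale propensity score (LSPS) model, preference scores, and the
empirical-equipoise diagnostic.

The propensity score S is the predicted probability of target-cohort
membership from an L1-regularized (Laplace prior) logistic regression on
all baseline covariates.  The prior variance is selected by k-fold
cross-validation maximizing out-of-fold log-likelihood over a log-spaced
grid.  The preference score F removes the cohort-size imbalance from S:
logit(F) = logit(S) - logit(P), with P the treated fraction.  Empirical
equipoise is the fraction of the (pre-matching) study population with
F in [0.3, 0.7]; an analysis with less than 35% in equipoise fails the
feasibility diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

#: log-spaced Laplace prior-variance grid searched by cross-validation,
#: anchored at the conventional 0.01 starting value
DEFAULT_PRIOR_VARIANCE_GRID: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)

SCORE_CLIP = 1e-10


@dataclass
class PSModel:
    """Fitted LSPS model and its in-sample scores."""

    intercept: float
    coefficients: np.ndarray            # dense but mostly zero (L1)
    selected_prior_variance: float
    cv_folds: int
    scores: np.ndarray                  # per-person P(target | X), clipped to (0,1)
    cv_loglik: dict[float, float] = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))


def _laplace_C(prior_variance: float) -> float:
    # Laplace prior with variance v has scale b = sqrt(v/2); the MAP
    # penalty is lambda = 1/b = sqrt(2/v), i.e. sklearn C = 1/lambda.
    return float(np.sqrt(prior_variance / 2.0))


def _fit_one(X, y, prior_variance: float, tol: float) -> LogisticRegression:
    import sklearn
    kwargs = (dict(l1_ratio=1.0) if sklearn.__version__ >= "1.8"
              else dict(penalty="l1"))
    return LogisticRegression(
        solver="liblinear", C=_laplace_C(prior_variance),
        tol=tol, fit_intercept=True, intercept_scaling=10.0,
        max_iter=2000, **kwargs).fit(X, y)


def fit_lsps(covariates: "sparse.spmatrix | np.ndarray", arm_labels: np.ndarray,
             cv_folds: int = 10,
             prior_variance_grid: tuple[float, ...] = DEFAULT_PRIOR_VARIANCE_GRID,
             tol: float = 2e-7, cv_tol: float = 1e-5, seed: int = 0) -> PSModel:
    """Fit the L1-regularized propensity model with CV-selected penalty.

    Parameters
    ----------
    covariates : sparse or dense (n_persons, n_covariates) matrix.
    arm_labels : boolean/0-1 vector; 1 = target cohort.
    cv_folds : folds for the prior-variance search.
    tol : convergence tolerance of the final fit.
    cv_tol : (looser) tolerance of the fold fits in the grid search.
    """
    y = np.asarray(arm_labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both arms required to fit a propensity model")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 persons per arm")
    X = sparse.csr_matrix(covariates) if not sparse.issparse(covariates) else covariates

    cv_loglik: dict[float, float] = {}
    if len(prior_variance_grid) > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        for v in prior_variance_grid:
            ll = 0.0
            for train, test in folds:
                m = _fit_one(X[train], y[train], v, cv_tol)
                p = np.clip(m.predict_proba(X[test])[:, 1], SCORE_CLIP, 1 - SCORE_CLIP)
                ll += float(np.sum(np.where(y[test] == 1, np.log(p), np.log1p(-p))))
            cv_loglik[v] = ll
        best_v = max(cv_loglik, key=cv_loglik.get)
    else:
        best_v = prior_variance_grid[0]

    model = _fit_one(X, y, best_v, tol)
    scores = model.predict_proba(X)[:, 1]
    if (scores <= SCORE_CLIP).any() or (scores >= 1 - SCORE_CLIP).any():
        warnings.warn("propensity scores at the boundary (possible separation); "
                      "clipping", RuntimeWarning, stacklevel=2)
    scores = np.clip(scores, SCORE_CLIP, 1 - SCORE_CLIP)
    return PSModel(intercept=float(model.intercept_[0]),
                   coefficients=model.coef_.ravel().copy(),
                   selected_prior_variance=float(best_v), cv_folds=cv_folds,
                   scores=scores, cv_loglik=cv_loglik)


def preference_score(scores: np.ndarray | float,
                     treated_fraction: float) -> np.ndarray | float:
    """Preference score F with logit(F) = logit(S) - logit(P)."""
    S = np.asarray(scores, dtype=float)
    P = float(treated_fraction)
    if not (0 < P < 1):
        raise ValueError("treated fraction must lie strictly in (0, 1)")
    if np.any(S <= 0) or np.any(S >= 1):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    F = expit(logit(S) - logit(P))
    return float(F) if np.isscalar(scores) else F


def equipoise_proportion(preference_scores: np.ndarray,
                         low: float = 0.3, high: float = 0.7) -> float:
    """Fraction of persons with preference score in [low, high], inclusive."""
    F = np.asarray(preference_scores, dtype=float)
    if F.size == 0:
        raise ValueError("empty preference-score vector")
    return float(np.mean((F >= low) & (F <= high)))


def equipoise_gate(proportion: float, threshold: float = 0.35) -> bool:
    """Pass iff the equipoise proportion is at least the threshold."""
    return proportion >= threshold
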