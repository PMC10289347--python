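"""Logistic score development: ML fit, backward Wald elimination, scoring.

The prognostic score is developed exactly as in the source protocol: fit a
multivariate logistic regression of tissue class (cancer = 1) on the
candidate covariates, repeatedly remove the covariate with the largest Wald
p-value while it exceeds alpha = 0.2, and define the score of a specimen as
the fitted linear predictor ("sum of logits") of the final model.  The
intercept is retained for interpretability; it cannot affect pairwise
concordance.

The ML fit is a hand-written damped Newton solver so that the
leave-one-pair-out machinery (hundreds of thousands of small fits over the
112-setting grid) stays fast; its coefficients, standard errors and Wald
p-values agree with standard implementations to numerical precision on
non-separated data.  Under complete separation the likelihood has no
maximiser; the solver detects the separation (all fitted probabilities at
their labels), stops, flags the fit, and the last iterate is used -- its
score ranking is still usable.  Backward elimination halts on a separated
fit rather than consult its Wald p-values: under separation every standard
error diverges (the Hauck-Donner effect) and the p-values would spuriously
eliminate even a perfectly discriminating covariate.  An optional ridge
penalty can be enabled to stabilise such fits; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["LogisticFit", "ScoreModel", "fit_logistic_arrays",
           "fit_logistic", "backward_eliminate", "score"]

_TOL = 1e-8
_MAX_ITER = 100


class DegenerateOutcomeError(ValueError):
    """The outcome has a single class; no logistic model can be fitted."""


@dataclass
class LogisticFit:
    """Raw ML fit: params[0] is the intercept, then one beta per covariate."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray     # Wald, vs standard normal; intercept included
    converged: bool
    n_iter: int
    n_obs: int
    separated: bool = False


@dataclass
class ScoreModel:
    """Final prognostic model: selected covariates and their coefficients."""

    covariates: tuple[str, ...]
    coefficients: dict[str, float]      # includes "intercept"
    converged: bool
    n_used: int
    eliminated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in self.covariates if c not in self.coefficients]
        if missing or not all(np.isfinite(v)
                              for v in self.coefficients.values()):
            raise ValueError("score model has missing/non-finite coefficients")


def fit_logistic_arrays(X: np.ndarray, y: np.ndarray,
                        ridge: float = 0.0) -> LogisticFit:
    """Newton ML fit of logit P(y=1) = b0 + X b.

    Stops when the max |score| falls below 1e-8 (at most 100 iterations);
    step-halving guards against overshoot.  ``ridge`` adds an optional L2
    penalty (not applied to the intercept).
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateOutcomeError("outcome takes a single value")
    n, p = X.shape
    A = np.empty((n, p + 1))
    A[:, 0] = 1.0
    A[:, 1:] = X
    beta = np.zeros(p + 1)
    penalty = np.full(p + 1, ridge)
    penalty[0] = 0.0

    def _loglike(b):
        eta = A @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum()
                     - 0.5 * (penalty * b * b).sum())

    ll = _loglike(beta)
    converged = False
    separated = False
    for it in range(1, _MAX_ITER + 1):
        eta = A @ beta
        mu = expit(eta)
        if ridge == 0.0 and np.max(np.abs(y - mu)) < 1e-3:
            separated = True       # complete separation: no ML maximiser
            break
        g = A.T @ (y - mu) - penalty * beta
        if np.max(np.abs(g)) < _TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (A * w[:, None]).T @ A + np.diag(penalty)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            break            # singular information: keep last finite iterate
        # step-halving: never accept a decrease in the (penalised) loglike
        scale = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglike(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            scale /= 2.0
        if not accepted:
            break            # no admissible step: keep last finite iterate
        beta = cand
        ll = ll_new
    else:
        it = _MAX_ITER

    eta = A @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (A * w[:, None]).T @ A + np.diag(penalty)
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        bse = np.full(p + 1, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, beta / bse, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, bse, pvals, converged, it, n, separated)


def _design(table, covariates, outcome_col="tissue", positive="cancer"):
    rows = table
    if "valid" in rows.columns:
        rows = rows[rows["valid"]]
    X = rows.loc[:, list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in valid rows")
    y = (rows[outcome_col] == positive).to_numpy(dtype=float)
    return X, y


def fit_logistic(table, covariates, ridge: float = 0.0
                 ) -> tuple[dict[str, float], dict[str, float]]:
    """Fit on a feature table; returns (coefficients, Wald p per covariate).

    ``table`` must carry a ``tissue`` column (cancer = 1, the event) and
    one numeric column per covariate; rows flagged invalid are dropped.
    Each class needs at least two valid rows.
    """
    X, y = _design(table, covariates)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DegenerateOutcomeError(
            "need >= 2 valid specimens in each tissue class")
    fit = fit_logistic_arrays(X, y, ridge=ridge)
    names = ["intercept", *covariates]
    coef = dict(zip(names, fit.params))
    pvals = dict(zip(covariates, fit.pvalues[1:]))
    return coef, pvals


def backward_eliminate(table, covariates, alpha: float = 0.2,
                       ridge: float = 0.0) -> ScoreModel:
    """Backward Wald elimination: drop the worst covariate while p > alpha.

    One covariate is removed per iteration (the largest Wald p) and the
    model refitted, since p-values change after each removal.  No re-entry
    step.  An empty final model (intercept only) is allowed.
    """
    X, y = _design(table, covariates)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DegenerateOutcomeError(
            "need >= 2 valid specimens in each tissue class")
    return _backward_eliminate_arrays(X, y, tuple(covariates),
                                      alpha=alpha, ridge=ridge)


def _backward_eliminate_arrays(X: np.ndarray, y: np.ndarray,
                               covariates: tuple[str, ...],
                               alpha: float = 0.2,
                               ridge: float = 0.0) -> ScoreModel:
    keep = list(range(len(covariates)))
    eliminated: list[str] = []
    fit = None
    while keep:
        fit = fit_logistic_arrays(X[:, keep], y, ridge=ridge)
        if fit.separated:
            break                  # Wald p-values are meaningless here
        p = fit.pvalues[1:]
        worst = int(np.argmax(p))
        if p[worst] <= alpha:
            break
        eliminated.append(covariates[keep[worst]])
        del keep[worst]
        fit = None
    if fit is None:       # all covariates eliminated: intercept-only model
        fit = fit_logistic_arrays(np.empty((y.size, 0)), y, ridge=ridge)
    names = tuple(covariates[i] for i in keep)
    coef = {"intercept": float(fit.params[0])}
    coef.update({name: float(b) for name, b in zip(names, fit.params[1:])})
    return ScoreModel(covariates=names, coefficients=coef,
                      converged=fit.converged, n_used=fit.n_obs,
                      eliminated=tuple(eliminated))


def score(model: ScoreModel, row) -> float:
    """Sum of logits for one specimen: intercept + sum_j beta_j * x_j.

    ``row`` is any mapping from covariate name to value.  Monotone in the
    predicted cancer probability, so score order equals probability order.
    """
    total = model.coefficients["intercept"]
    for name in model.covariates:
        try:
            x = row[name]
        except KeyError as exc:
            raise KeyError(f"row is missing covariate {name!r}") from exc
        if not np.isfinite(x):
            raise ValueError(f"covariate {name!r} is not finite")
        total += model.coefficients[name] * float(x)
    return float(total)
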