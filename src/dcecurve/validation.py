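"""Leave-one-pair-out cross-validated C-statistic and grid trend analysis.

The discriminatory power of the score is estimated without an external
validation set: for every (case, control) pair -- case a cancer specimen,
control a normal specimen -- the whole score development (backward Wald
elimination included) is re-run on the data with both involved subjects'
specimens removed, the two held-out specimens are scored, and the pair is
concordant iff the case's score is strictly greater than the control's.
The C-statistic is the fraction of concordant pairs among all possible
pairs; ties (and folds whose training fit fails) count as non-concordant,
keeping the denominator fixed at n_cases * n_controls.

Two leave-out conventions are offered.  ``subject`` (default, strictest
leakage control) drops every specimen belonging to either held-out
specimen's subject -- relevant because most subjects contribute both a
cancer and a normal specimen -- while ``specimen`` drops only the two
held-out specimens themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import AcquisitionSetting
from .scoring import _backward_eliminate_arrays

__all__ = ["ValidationResult", "TrendResult", "c_statistic_oracle",
           "lopo_c_statistic", "trend_analysis"]


@dataclass
class ValidationResult:
    """LOPO cross-validation outcome for one acquisition setting."""

    c_statistic: float
    n_pairs: int
    n_concordant: float
    n_failed_fits: int
    final_model_covariates: tuple[str, ...]
    n_valid_cases: int
    n_valid_controls: int
    n_invalid: int
    setting: AcquisitionSetting | None = None
    pair_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_statistic <= 1.0):
            raise ValueError("C-statistic outside [0, 1]")


@dataclass
class TrendResult:
    """OLS linear trend of C-statistics against one grid dimension."""

    predictor: str            # "resolution_s" or "length_min"
    slope: float
    ci_low: float
    ci_high: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must contain the slope")


def c_statistic_oracle(case_scores, control_scores,
                       tie_rule: str = "strict") -> float:
    """Brute-force concordance over all (case, control) score pairs.

    The reference implementation of the pair bookkeeping: a plain double
    loop, strict-greater rule (``tie_rule='half'`` gives ties 0.5 credit).
    """
    case_scores = list(case_scores)
    control_scores = list(control_scores)
    if not case_scores or not control_scores:
        raise ValueError("need at least one case and one control score")
    concordant = 0.0
    for cs in case_scores:
        for ns in control_scores:
            if cs > ns:
                concordant += 1.0
            elif cs == ns and tie_rule == "half":
                concordant += 0.5
    return concordant / (len(case_scores) * len(control_scores))


def lopo_c_statistic(table: pd.DataFrame,
                     covariates,
                     alpha: float = 0.2,
                     leave_out: str = "subject",
                     tie_rule: str = "strict",
                     ridge: float = 0.0,
                     setting: AcquisitionSetting | None = None,
                     keep_pair_log: bool = False) -> ValidationResult:
    """Leave-one-pair-out cross-validated C-statistic.

    ``table`` is a feature table (one row per specimen with ``subject_id``,
    ``tissue``, ``valid`` and the covariate columns).  Rows flagged invalid
    take no part, as case, control or training data.  For every pair the
    full score development is re-run on the training split; a failed fit
    (single-class training data, all-NaN step) counts the pair as
    non-concordant without touching the denominator.
    """
    if tie_rule not in ("strict", "half"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    if leave_out not in ("subject", "specimen"):
        raise ValueError(f"unknown leave-out unit {leave_out!r}")
    rows = table[table["valid"]] if "valid" in table.columns else table
    n_invalid = len(table) - len(rows)
    X = rows.loc[:, list(covariates)].to_numpy(dtype=float)
    y = (rows["tissue"] == "cancer").to_numpy()
    subjects = rows["subject_id"].to_numpy()
    case_idx = np.flatnonzero(y)
    control_idx = np.flatnonzero(~y)
    if case_idx.size < 2 or control_idx.size < 2:
        raise ValueError("need >= 2 valid specimens per tissue class")

    covariates = tuple(covariates)
    n_pairs = case_idx.size * control_idx.size
    concordant = 0.0
    n_failed = 0
    log_rows = [] if keep_pair_log else None
    n = len(rows)
    for i in case_idx:
        for j in control_idx:
            if leave_out == "subject":
                train = ~((subjects == subjects[i]) | (subjects == subjects[j]))
            else:
                train = np.ones(n, dtype=bool)
                train[i] = train[j] = False
            yt = y[train]
            outcome = np.nan
            s_case = s_control = np.nan
            try:
                if yt.sum() < 2 or (~yt).sum() < 2:
                    raise ValueError("degenerate training split")
                model = _backward_eliminate_arrays(
                    X[train], yt.astype(float), covariates,
                    alpha=alpha, ridge=ridge)
                beta = np.array([model.coefficients[c]
                                 for c in model.covariates])
                cols = [covariates.index(c) for c in model.covariates]
                s_case = model.coefficients["intercept"] + X[i, cols] @ beta
                s_control = model.coefficients["intercept"] + X[j, cols] @ beta
                if not (np.isfinite(s_case) and np.isfinite(s_control)):
                    raise ValueError("non-finite held-out score")
                if s_case > s_control:
                    outcome = 1.0
                elif s_case == s_control and tie_rule == "half":
                    outcome = 0.5
                else:
                    outcome = 0.0
                concordant += outcome
            except (ValueError, np.linalg.LinAlgError):
                n_failed += 1
                outcome = 0.0
            if log_rows is not None:
                log_rows.append((rows["specimen_id"].iat[i],
                                 rows["specimen_id"].iat[j],
                                 s_case, s_control, outcome))

    # the reported covariate set comes from the all-data fit
    full_model = _backward_eliminate_arrays(
        X, y.astype(float), covariates, alpha=alpha, ridge=ridge)
    return ValidationResult(
        c_statistic=concordant / n_pairs,
        n_pairs=n_pairs,
        n_concordant=concordant,
        n_failed_fits=n_failed,
        final_model_covariates=full_model.covariates,
        n_valid_cases=int(case_idx.size),
        n_valid_controls=int(control_idx.size),
        n_invalid=n_invalid,
        setting=setting,
        pair_log=(pd.DataFrame(log_rows,
                               columns=["case", "control", "case_score",
                                        "control_score", "concordant"])
                  if log_rows is not None else None),
    )


def trend_analysis(results, predictors=("resolution_s", "length_min"),
                   joint: bool = False) -> list[TrendResult]:
    """OLS linear trend of the C-statistic across the setting grid.

    Default: one univariate regression of C on each predictor.  With
    ``joint=True`` a single bivariate model is fitted instead and each
    reported slope adjusts for the other predictor.
    """
    cells = [(r.setting.resolution_s, r.setting.length_min, r.c_statistic)
             for r in results
             if r is not None and r.setting is not None
             and np.isfinite(r.c_statistic)]
    if len(cells) < 3:
        raise ValueError("need >= 3 grid cells for a trend analysis")
    df = pd.DataFrame(cells, columns=["resolution_s", "length_min", "c"])
    out = []
    if joint:
        X = sm.add_constant(df[list(predictors)])
        fit = sm.OLS(df["c"], X).fit()
        ci = fit.conf_int(alpha=0.05)
        for name in predictors:
            out.append(TrendResult(name, float(fit.params[name]),
                                   float(ci.loc[name, 0]),
                                   float(ci.loc[name, 1]), len(df)))
    else:
        for name in predictors:
            X = sm.add_constant(df[[name]])
            fit = sm.OLS(df["c"], X).fit()
            ci = fit.conf_int(alpha=0.05)
            out.append(TrendResult(name, float(fit.params[name]),
                                   float(ci.loc[name, 0]),
                                   float(ci.loc[name, 1]), len(df)))
    return out
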