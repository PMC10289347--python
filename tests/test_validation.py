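import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import dcecurve as dc


def make_cohort_table(rng, n_both=3, n_cancer_only=2, n_normal_only=2,
                      shift=1.0, n_covariates=2):
    """Small feature table with paired subjects and Gaussian covariates."""
    rows = []
    subj = 0
    for _ in range(n_both):
        subj += 1
        for tissue in ("cancer", "normal"):
            rows.append((f"s{subj}-{tissue[0]}", f"p{subj}", tissue))
    for _ in range(n_cancer_only):
        subj += 1
        rows.append((f"s{subj}-c", f"p{subj}", "cancer"))
    for _ in range(n_normal_only):
        subj += 1
        rows.append((f"s{subj}-n", f"p{subj}", "normal"))
    df = pd.DataFrame(rows, columns=["specimen_id", "subject_id", "tissue"])
    names = [f"x{j}" for j in range(n_covariates)]
    for name in names:
        df[name] = rng.normal(size=len(df)) \
            + shift * (df["tissue"] == "cancer")
    df["valid"] = True
    return df, names


def linearly_separable(X, y):
    """Exact LP feasibility check for (weak margin) linear separability."""
    from scipy.optimize import linprog
    s = 2.0 * np.asarray(y, dtype=float) - 1.0
    A = np.column_stack([np.ones(len(s)), np.asarray(X, dtype=float)])
    res = linprog(np.zeros(A.shape[1]), A_ub=-(s[:, None] * A),
                  b_ub=-np.ones(len(s)),
                  bounds=[(None, None)] * A.shape[1], method="highs")
    return res.status == 0


def cohort_has_separable_fold(table, names):
    """True if any LOPO training split is linearly separable.

    Where a fold separates, the logistic MLE does not exist and two solvers
    legitimately stop at different iterates, so exact cross-implementation
    equality is only defined on separation-free cohorts.
    """
    valid = table[table["valid"]]
    y = (valid["tissue"] == "cancer").to_numpy()
    X = valid[names].to_numpy()
    subjects = valid["subject_id"].to_numpy()
    for si in np.unique(subjects[y]):
        for sj in np.unique(subjects[~y]):
            train = ~np.isin(subjects, [si, sj])
            if min(y[train].sum(), (~y[train]).sum()) < 2:
                continue
            if linearly_separable(X[train], y[train]):
                return True
    return False


# ---------------------------------------------------------------------------
# independent reference implementation (statsmodels, plain loops)
# ---------------------------------------------------------------------------

def _reference_develop_score(train: pd.DataFrame, names, alpha=0.2):
    """Backward Wald elimination via statsmodels GLM, halting on separation."""
    keep = list(names)
    y = (train["tissue"] == "cancer").astype(float).to_numpy()
    while True:
        X = sm.add_constant(train[keep].to_numpy(), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if np.max(np.abs(y - res.fittedvalues)) < 1e-3:
            break                                  # separated: stop removing
        if not keep:
            break
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            break
        del keep[worst]
    return keep, res.params


def reference_lopo(table: pd.DataFrame, names, alpha=0.2):
    """Plain-loop LOPO C: subject leave-out, strict-greater concordance."""
    valid = table[table["valid"]]
    cases = valid[valid["tissue"] == "cancer"]
    controls = valid[valid["tissue"] == "normal"]
    concordant, total = 0, 0
    for _, case in cases.iterrows():
        for _, control in controls.iterrows():
            total += 1
            train = valid[~valid["subject_id"].isin(
                [case["subject_id"], control["subject_id"]])]
            if min((train["tissue"] == "cancer").sum(),
                   (train["tissue"] == "normal").sum()) < 2:
                continue
            try:
                keep, params = _reference_develop_score(train, names, alpha)
            except Exception:
                continue
            s_case = params[0] + sum(
                b * case[k] for k, b in zip(keep, params[1:]))
            s_control = params[0] + sum(
                b * control[k] for k, b in zip(keep, params[1:]))
            if s_case > s_control:
                concordant += 1
    return concordant / total


class TestCStatisticOracle:
    def test_enumerated_examples(self):
        assert dc.c_statistic_oracle([2, 3], [1, 2.5]) == pytest.approx(0.75)
        assert dc.c_statistic_oracle([1], [1]) == 0.0
        assert dc.c_statistic_oracle([1], [1], tie_rule="half") == 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=8),
           st.lists(st.integers(-5, 5), min_size=1, max_size=8))
    def test_antisymmetry_up_to_ties(self, cases, controls):
        forward = dc.c_statistic_oracle(cases, controls)
        backward = dc.c_statistic_oracle(controls, cases)
        ties = np.mean([c == n for c in cases for n in controls])
        assert forward + backward + ties == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.lists(st.floats(-10, 10), min_size=1, max_size=8))
    def test_half_rule_matches_mann_whitney_auc(self, cases, controls):
        from sklearn.metrics import roc_auc_score
        y = [1] * len(cases) + [0] * len(controls)
        if len(set(y)) < 2:
            return
        ours = dc.c_statistic_oracle(cases, controls, tie_rule="half")
        ref = roc_auc_score(y, list(cases) + list(controls))
        assert ours == pytest.approx(ref)


class TestLopoCStatistic:
    def test_perfectly_separating_covariate_gives_c_one(self):
        rng = np.random.default_rng(0)
        table, names = make_cohort_table(rng, n_both=0, n_cancer_only=5,
                                         n_normal_only=5, shift=0.0)
        table["x0"] = np.where(table["tissue"] == "cancer", 10.0, 0.0) \
            + rng.normal(0, 0.1, len(table))
        res = dc.lopo_c_statistic(table, ["x0"])
        assert res.c_statistic == 1.0
        assert res.n_pairs == 25

    def test_constant_scores_count_zero_under_strict_rule(self):
        rng = np.random.default_rng(1)
        table, names = make_cohort_table(rng, shift=0.5)
        table["x0"] = 7.0                       # constant: empty model, ties
        res = dc.lopo_c_statistic(table, ["x0"])
        assert res.c_statistic == 0.0
        half = dc.lopo_c_statistic(table, ["x0"], tie_rule="half")
        assert half.c_statistic == 0.5

    def test_pipeline_matches_reference_implementation(self):
        """Dual-route check against statsmodels on separation-free cohorts.

        On cohorts where no training fold is linearly separable the MLE is
        unique, so the hand-written Newton pipeline and the plain-loop
        statsmodels reference must produce the same elimination path,
        scores and hence exactly the same C.
        """
        rng = np.random.default_rng(2025)
        n_checked = 0
        for _ in range(200):
            # one covariate, modest shift: small cohorts rarely separate
            table, names = make_cohort_table(
                rng, n_both=int(rng.integers(3, 5)),
                n_cancer_only=int(rng.integers(1, 3)),
                n_normal_only=int(rng.integers(1, 3)),
                shift=float(rng.uniform(0, 0.8)), n_covariates=1)
            if cohort_has_separable_fold(table, names):
                continue
            ours = dc.lopo_c_statistic(table, names).c_statistic
            ref = reference_lopo(table, names)
            assert ours == pytest.approx(ref, abs=1e-12)
            n_checked += 1
            if n_checked == 25:
                break
        assert n_checked == 25

    def test_bookkeeping_matches_pair_log(self):
        rng = np.random.default_rng(7)
        table, names = make_cohort_table(rng, n_both=4, shift=0.8)
        res = dc.lopo_c_statistic(table, names, keep_pair_log=True)
        log = res.pair_log
        assert len(log) == res.n_pairs
        # replay the strict rule on the logged held-out scores
        replay = float(np.sum(log["case_score"] > log["control_score"]))
        assert replay == res.n_concordant
        assert res.c_statistic == replay / res.n_pairs

    def test_monotone_transform_leaves_c_unchanged(self):
        rng = np.random.default_rng(3)
        table, names = make_cohort_table(rng, shift=1.0)
        res = dc.lopo_c_statistic(table, names, keep_pair_log=True)
        log = res.pair_log.dropna()
        transformed = dc.c_statistic_oracle(
            np.tanh(log["case_score"] / 10), np.tanh(log["control_score"] / 10))
        raw = dc.c_statistic_oracle(log["case_score"], log["control_score"])
        assert transformed == pytest.approx(raw)

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(4)
        table, names = make_cohort_table(rng, shift=0.7)
        res = dc.lopo_c_statistic(table, names, keep_pair_log=True)
        n_non = (res.pair_log["concordant"] == 0.0).sum()
        assert n_non + res.n_concordant == res.n_pairs
        assert res.n_pairs == res.n_valid_cases * res.n_valid_controls

    def test_invalid_rows_excluded_everywhere(self):
        rng = np.random.default_rng(5)
        table, names = make_cohort_table(rng, n_both=4, shift=1.0)
        table.loc[table.index[0], "valid"] = False
        res = dc.lopo_c_statistic(table, names)
        assert res.n_invalid == 1
        assert res.n_pairs == res.n_valid_cases * res.n_valid_controls

    def test_subject_leave_out_drops_partner_specimen(self):
        # a paired subject's other-tissue specimen must never train the
        # model that is tested on it
        rng = np.random.default_rng(6)
        table, names = make_cohort_table(rng, n_both=3, n_cancer_only=1,
                                         n_normal_only=1, shift=0.5)
        strict = dc.lopo_c_statistic(table, names, leave_out="subject")
        loose = dc.lopo_c_statistic(table, names, leave_out="specimen")
        assert strict.n_pairs == loose.n_pairs   # denominator unaffected


class TestTrendAnalysis:
    def _results(self, c_values):
        out = []
        for (res, length), c in zip(
                [(r, l) for l in dc.LENGTHS_MIN for r in dc.RESOLUTIONS_S],
                c_values):
            out.append(dc.ValidationResult(
                c_statistic=float(c), n_pairs=10, n_concordant=10 * float(c),
                n_failed_fits=0, final_model_covariates=(),
                n_valid_cases=5, n_valid_controls=2, n_invalid=0,
                setting=dc.AcquisitionSetting(res, length)))
        return out

    def test_constant_c_gives_zero_slopes(self):
        results = self._results(np.full(112, 0.7))
        for tr in dc.trend_analysis(results):
            assert tr.slope == pytest.approx(0.0, abs=1e-12)
            assert tr.ci_low <= 1e-12 and tr.ci_high >= -1e-12

    def test_exact_linear_trend_recovered(self):
        settings_list = dc.grid_settings()
        c = [0.5 + 0.001 * s.resolution_s for s in settings_list]
        results = self._results(c)
        res_trend = [t for t in dc.trend_analysis(results)
                     if t.predictor == "resolution_s"][0]
        assert res_trend.slope == pytest.approx(0.001, rel=1e-10)

    def test_univariate_and_joint_agree_on_orthogonal_grid(self):
        # the full factorial grid is balanced, so adjusting for the other
        # factor must not change either slope
        settings_list = dc.grid_settings()
        c = [0.5 + 0.001 * s.resolution_s + 0.002 * s.length_min
             for s in settings_list]
        results = self._results(c)
        uni = {t.predictor: t.slope for t in dc.trend_analysis(results)}
        joint = {t.predictor: t.slope
                 for t in dc.trend_analysis(results, joint=True)}
        for k in uni:
            assert uni[k] == pytest.approx(joint[k], rel=1e-8)

    def test_too_few_cells_rejected(self):
        results = self._results(np.full(112, 0.7))[:2]
        with pytest.raises(ValueError):
            dc.trend_analysis(results)


def test_permutation_null_centres_on_half():
    """With labels permuted, LOPO C (full model retained) averages 0.5."""
    rng = np.random.default_rng(99)
    base, names = make_cohort_table(rng, n_both=0, n_cancer_only=20,
                                    n_normal_only=20, shift=1.0)
    cs = []
    for _ in range(200):
        table = base.copy()
        table["tissue"] = rng.permutation(base["tissue"].to_numpy())
        res = dc.lopo_c_statistic(table, names, alpha=np.inf,
                                  leave_out="specimen")
        cs.append(res.c_statistic)
    mean_c = np.mean(cs)
    se = np.std(cs, ddof=1) / np.sqrt(len(cs))
    assert abs(mean_c - 0.5) < 3 * max(se, 1e-3)
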