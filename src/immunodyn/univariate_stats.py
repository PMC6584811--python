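"""Per-feature univariate statistics, ROC/AUC, and confounder regression.

The group-comparison test is gated on per-group Shapiro-Wilk normality:
Student t-test when both groups look normal, two-sided Mann-Whitney
otherwise. AUC is computed once here (U-statistic form) and shared with
the predictive model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

CONFOUNDERS = ("BMI", "autoimmune", "chronic_hypertension", "type2_diabetes")


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("roc_auc requires both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


@dataclass
class FeatureTestResult:
    feature: str
    test: str                   # "t-test" | "mann-whitney" | "degenerate"
    statistic: float
    p_value: float
    auc: float
    mean_control: float
    mean_case: float
    median_control: float
    median_case: float
    shapiro_p_control: float | None = None
    shapiro_p_case: float | None = None


def compare_feature(values, labels, feature: str = "",
                    alpha_normality: float = 0.05) -> FeatureTestResult:
    """Shapiro-gated two-group comparison plus AUC for one feature."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    g0 = values[labels == 0]
    g1 = values[labels == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise ValidationError("compare_feature needs >= 3 observations per group")

    summary = dict(mean_control=float(g0.mean()), mean_case=float(g1.mean()),
                   median_control=float(np.median(g0)),
                   median_case=float(np.median(g1)))

    if np.ptp(g0) == 0 and np.ptp(g1) == 0 and g0[0] == g1[0]:
        logger.warning("feature %s constant in both groups", feature)
        return FeatureTestResult(feature, "degenerate", 0.0, 1.0, 0.5,
                                 **summary)

    def shapiro_p(g):
        if np.ptp(g) == 0:
            return 0.0  # a constant group is maximally non-normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(g).pvalue)

    sp0, sp1 = shapiro_p(g0), shapiro_p(g1)
    if sp0 >= alpha_normality and sp1 >= alpha_normality:
        res = stats.ttest_ind(g1, g0, equal_var=True)
        test, statistic, p = "t-test", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        test, statistic, p = "mann-whitney", float(res.statistic), float(res.pvalue)
    auc = roc_auc(values, labels)
    return FeatureTestResult(feature, test, statistic, p, auc,
                             shapiro_p_control=sp0, shapiro_p_case=sp1,
                             **summary)


def compare_features(frame: pd.DataFrame, labels,
                     alpha_normality: float = 0.05,
                     bh_correction: bool = False) -> pd.DataFrame:
    """Column-wise group comparison; optional Benjamini-Hochberg column."""
    rows = [compare_feature(frame[c].to_numpy(), labels, feature=c,
                            alpha_normality=alpha_normality)
            for c in frame.columns]
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (sum of tables as or less probable)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("fisher_exact expects a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class ConfounderResult:
    feature: str
    status_coef: float
    status_p: float
    coefs: dict[str, float]
    r_squared: float
    rank_deficient: bool = False


def confounder_regression(values, sheet: pd.DataFrame,
                          feature: str = "") -> ConfounderResult:
    """OLS of one feature on case status plus the four comorbidity
    covariates; Wald p-value for the status coefficient.

    Rank-deficient designs are flagged (pinv solution reported), never
    silently reduced.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    missing = [c for c in CONFOUNDERS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet lacks covariates: {missing}")
    status = (sheet["group"].astype(str) == "case").astype(float).to_numpy()
    Xdf = pd.DataFrame({"status": status})
    for c in CONFOUNDERS:
        Xdf[c] = sheet[c].astype(float).to_numpy()
    X = sm.add_constant(Xdf)
    if len(values) <= X.shape[1]:
        raise ValidationError("too few observations for confounder regression")
    rank_deficient = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    if rank_deficient:
        logger.warning("rank-deficient confounder design for %s", feature)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(values, X).fit()
    return ConfounderResult(
        feature=feature,
        status_coef=float(fit.params["status"]),
        status_p=float(fit.pvalues["status"]),
        coefs={c: float(fit.params[c]) for c in CONFOUNDERS},
        r_squared=float(fit.rsquared),
        rank_deficient=bool(rank_deficient))


def confounder_table(frame: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for c in frame.columns:
        r = confounder_regression(frame[c].to_numpy(), sheet, feature=c)
        row = {"feature": r.feature, "status_coef": r.status_coef,
               "status_p": r.status_p, "r_squared": r.r_squared,
               "rank_deficient": r.rank_deficient}
        row.update({f"coef_{k}": v for k, v in r.coefs.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def cohort_summary(sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic summary with the appropriate two-group test:
    t-test for continuous covariates, Fisher exact for binary flags."""
    is_case = sheet["group"].astype(str) == "case"
    rows = []
    for col in sheet.columns:
        if col in ("patient", "group"):
            continue
        vals = pd.to_numeric(sheet[col], errors="coerce")
        g0, g1 = vals[~is_case], vals[is_case]
        binary = set(vals.dropna().unique()) <= {0, 1}
        if binary:
            table = [[int(g0.sum()), int(len(g0) - g0.sum())],
                     [int(g1.sum()), int(len(g1) - g1.sum())]]
            p = fisher_exact(table)
            rows.append({"variable": col, "test": "fisher",
                         "control": f"{int(g0.sum())}/{len(g0)}",
                         "case": f"{int(g1.sum())}/{len(g1)}", "p_value": p})
        else:
            p = float(stats.ttest_ind(g1, g0, equal_var=True).pvalue) \
                if np.ptp(vals.dropna()) > 0 else 1.0
            rows.append({"variable": col, "test": "t-test",
                         "control": f"{g0.mean():.2f} ± {g0.std():.2f}",
                         "case": f"{g1.mean():.2f} ± {g1.std():.2f}",
                         "p_value": p})
    return pd.DataFrame(rows).set_index("variable")
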