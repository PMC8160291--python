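"""Outcome statistics: ROC/cutoff, group comparisons, survival, reliability."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0 <= self.auc <= 1):
            raise ValueError("AUC must lie in [0, 1]")
        for v in (self.sensitivity, self.specificity):
            if not (0 <= v <= 1):
                raise ValueError("sensitivity/specificity must lie in [0, 1]")


@dataclass
class SurvivalFit:
    km_curves: dict = field(default_factory=dict)   # group -> (times, survival)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cox_table: pd.DataFrame | None = None


def roc_auc_and_cutoff(scores, labels) -> ROCResult:
    """AUC (Mann-Whitney form, ties counted 1/2) and the Youden-optimal cutoff.

    The cutoff is the observed score maximizing ``sensitivity +
    specificity - 1`` under the "positive when score > cutoff" calling
    convention; ties in the Youden index are broken toward higher
    specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(wins / (len(pos) * len(neg)))

    best = None
    for t in np.unique(scores):
        sens = float((pos > t).mean())
        spec = float((neg <= t).mean())
        j = sens + spec - 1.0
        key = (j, spec, t)
        if best is None or key > (best[0], best[1], best[2]):
            best = (j, spec, t, sens)
    _, spec, cutoff, sens = best
    return ROCResult(auc=auc, cutoff=float(cutoff), sensitivity=sens, specificity=spec)


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC polygon (FPR, TPR), for plotting and trapezoid checks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    tpr = np.array([(pos > t).mean() if len(pos) else 0.0 for t in thresholds])
    fpr = np.array([(neg > t).mean() if len(neg) else 0.0 for t in thresholds])
    return fpr, tpr


def km_logrank(times, events, groups) -> SurvivalFit:
    """Kaplan-Meier product-limit curves per group plus the log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    fit = SurvivalFit()
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        fit.km_curves[g] = (sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
    if len(fit.km_curves) >= 2:
        res = multivariate_logrank_test(times, groups, events)
        fit.logrank_stat = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    return fit


def cox_ph(covariates: pd.DataFrame, times, events, gate_p: float = 0.05,
           penalizer: float = 0.0) -> SurvivalFit:
    """Univariate Cox per covariate, then a joint multivariate refit.

    Only covariates with univariate p below ``gate_p`` enter the
    multivariate model.  Ties are handled by Efron's method (lifelines
    default).  Returns hazard ratios with 95% CIs flagged by stage.
    A small ridge ``penalizer`` stabilizes near-separated covariates on
    small cohorts; perfect separation without one surfaces as a
    non-convergence error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() < 1:
        raise ValueError("no events observed")

    rows = []
    passed = []
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} has zero variance")
        df = pd.DataFrame({col: covariates[col].to_numpy(),
                           "T": times, "E": events})
        f = CoxPHFitter(penalizer=penalizer)
        try:
            f.fit(df, duration_col="T", event_col="E")
        except Exception as exc:  # noqa: BLE001 - surfaced as non-convergence
            raise RuntimeError(f"univariate Cox failed to converge for {col!r}: {exc}")
        s = f.summary.loc[col]
        rows.append({"covariate": col, "stage": "univariate",
                     "HR": float(s["exp(coef)"]),
                     "CI_lower": float(s["exp(coef) lower 95%"]),
                     "CI_upper": float(s["exp(coef) upper 95%"]),
                     "p": float(s["p"])})
        if rows[-1]["p"] < gate_p:
            passed.append(col)

    if passed:
        df = covariates[passed].copy()
        df["T"], df["E"] = times, events
        f = CoxPHFitter(penalizer=penalizer)
        try:
            f.fit(df, duration_col="T", event_col="E")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"multivariate Cox failed to converge: {exc}")
        for col in passed:
            s = f.summary.loc[col]
            rows.append({"covariate": col, "stage": "multivariate",
                         "HR": float(s["exp(coef)"]),
                         "CI_lower": float(s["exp(coef) lower 95%"]),
                         "CI_upper": float(s["exp(coef) upper 95%"]),
                         "p": float(s["p"])})
    return SurvivalFit(cox_table=pd.DataFrame(rows))


def cohort_table_stats(
    cohort: pd.DataFrame,
    group_col: str = "event",
    categorical: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Categorical variables: chi-square without continuity correction, or
    Fisher's exact test when any expected cell count is below 5 (2x2
    only).  Continuous variables: two-sided Mann-Whitney U.  Variables
    with a single observed level are skipped with a warning.
    """
    g = cohort[group_col].astype(int)
    if g.nunique() != 2:
        raise ValueError("grouping column must have exactly two levels")
    rows = []
    for var in categorical:
        tab = pd.crosstab(cohort[var], g)
        if tab.shape[0] < 2:
            warnings.warn(f"variable {var!r} has a single level; skipped", stacklevel=2)
            continue
        chi2, p, _, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
        test = "chi-square"
        stat = float(chi2)
        if (expected < 5).any() and tab.shape == (2, 2):
            stat, p = sps.fisher_exact(tab.to_numpy())
            test = "fisher"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p)})
    for var in continuous:
        a = cohort.loc[g == 0, var].to_numpy()
        b = cohort.loc[g == 1, var].to_numpy()
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"variable": var, "test": "mann-whitney", "statistic": float(u),
                     "p": float(p)})
    return pd.DataFrame(rows)


def group_rates(counts) -> list[float]:
    """Event proportion per group from a (group x [events, non-events]) table.

    Returned in percent, rounded to one decimal.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("expected a (n_groups, 2) table of [events, non-events]")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every group must have a positive total")
    return [round(float(100.0 * e / t), 1) for e, t in zip(counts[:, 0], totals)]


def icc_agreement(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects-by-raters table.  With mean squares from the
    two-way layout (rows MSR, columns MSC, error MSE):
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(ss_rows, 0.0):
        warnings.warn("zero between-subject variance; ICC reported as 0", stacklevel=2)
        return 0.0
    if denom == 0:
        warnings.warn("degenerate ratings table; ICC reported as 0", stacklevel=2)
        return 0.0
    return float((msr - mse) / denom)
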