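"""Outcome statistics relating fibrosis change to arrhythmia recurrence.

Group comparisons (Student's t, Fisher's exact), logistic models with
Wald odds-ratio confidence intervals, ROC/AUC, and Kaplan–Meier with the
two-group log-rank test — the analysis layer applied to the per-patient
fibrosis deltas.  No multiple-testing correction is applied.

AUC is computed exactly as the tie-corrected concordance probability
P(score_pos > score_neg) + ½·P(tie) via the rank (Mann–Whitney) formula;
the curve itself comes from a standard threshold sweep.  Fisher's exact
two-sided p uses the probability-ordering convention (sum of all tables
as or less probable than the observed one), the convention of mainstream
statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import SeparationError, StatisticsError

__all__ = [
    "RocCurve",
    "CovariateEffect",
    "SurvivalFit",
    "roc_auc",
    "logistic_fit",
    "km_logrank",
    "group_compare",
    "analyze_cohort",
    "CohortReport",
]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 − specificity
    tpr: np.ndarray  # sensitivity
    auc: float

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def roc_auc(score, label) -> RocCurve:
    """ROC curve and exact tie-corrected AUC.

    AUC = P(score⁺ > score⁻) + ½ P(score⁺ = score⁻), computed through
    midranks: (Σ ranks of positives − n₁(n₁+1)/2) / (n₁ n₀).
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    if score.shape != label.shape or score.ndim != 1:
        raise StatisticsError("score and label must be equal-length 1D arrays")
    n1 = int(label.sum())
    n0 = int(len(label) - n1)
    if n1 == 0 or n0 == 0:
        raise StatisticsError("both outcome classes must be present")
    ranks = stats.rankdata(score)
    auc = (float(ranks[label == 1].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(label, score, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc))


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class CovariateEffect:
    name: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def _separates(y: np.ndarray, X: pd.DataFrame) -> bool:
    """Complete separation check: some covariate splits the classes."""
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        a, b = x[y == 1], x[y == 0]
        if len(a) and len(b) and (a.min() > b.max() or a.max() < b.min()):
            return True
    return False


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> list:
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
    except Exception as exc:
        if ("Separation" in type(exc).__name__
                or "separation" in str(exc).lower() or _separates(y, X)):
            raise SeparationError(f"perfect separation: {exc}") from exc
        raise StatisticsError(str(exc)) from exc
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(bse)) or np.any(bse > 1e3):
        raise SeparationError("perfect or quasi-perfect separation detected "
                              "(unbounded standard errors); no estimates returned")
    out = []
    for name in X.columns:
        b = float(res.params[name])
        se = float(res.bse[name])
        out.append(CovariateEffect(
            name=name, coef=b, odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.959963984540054 * se)),
            ci_high=float(np.exp(b + 1.959963984540054 * se)),
            p_value=float(res.pvalues[name]),
        ))
    return out


def logistic_fit(y, X, mode: str = "univariate") -> list:
    """Maximum-likelihood logistic fits with Wald 95% CIs on the OR scale.

    ``mode="univariate"`` fits one single-covariate model per column;
    ``mode="multivariate"`` fits one joint model.  Perfect separation is
    detected and raised as :class:`SeparationError` (no estimates).
    """
    y = np.asarray(y).astype(float)
    X = pd.DataFrame(X)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatisticsError("outcome must be binary 0/1")
    if len(X) <= X.shape[1] + 1:
        raise StatisticsError("need n > number of covariates + 1")
    for col in X.columns:
        if float(np.std(X[col].to_numpy(dtype=float))) == 0.0:
            raise StatisticsError(f"covariate {col!r} is constant")
    if mode == "univariate":
        effects = []
        for col in X.columns:
            effects.extend(_fit_logit(y, X[[col]]))
        return effects
    if mode == "multivariate":
        return _fit_logit(y, X)
    raise ValueError(f"mode must be 'univariate' or 'multivariate', got {mode!r}")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Kaplan–Meier fits per group plus the two-group log-rank test."""

    groups: list
    timelines: dict      # group -> event/censoring times (sorted)
    survival: dict       # group -> step-function survival values
    at_risk: dict        # group -> subjects at risk entering each time
    logrank_statistic: float | None
    logrank_p: float | None

    def survival_at(self, group, t: float) -> float:
        """Step-function value S(t) for one group."""
        tl = self.timelines[group]
        sv = self.survival[group]
        idx = np.searchsorted(tl, t, side="right") - 1
        return 1.0 if idx < 0 else float(sv[idx])


def km_logrank(times, events, group=None) -> SurvivalFit:
    """Product-limit estimator per group; log-rank χ² (1 df) for 2 groups."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) == 0 or events.sum() < 1:
        raise StatisticsError("need at least one event")
    if group is None:
        group = np.zeros(len(times), dtype=int)
    group = np.asarray(group)
    labels = sorted(pd.unique(group).tolist())
    if any((group == g).sum() == 0 for g in labels):
        raise StatisticsError("empty group")

    timelines, survival, at_risk = {}, {}, {}
    for g in labels:
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        sv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        timelines[g] = tl
        survival[g] = sv
        at_risk[g] = kmf.event_table["at_risk"].to_numpy(dtype=float)

    stat = p = None
    if len(labels) == 2:
        sel = group == labels[0]
        res = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
        stat = float(res.test_statistic)
        p = float(min(res.p_value, 1.0))
    return SurvivalFit(groups=labels, timelines=timelines, survival=survival,
                       at_risk=at_risk, logrank_statistic=stat, logrank_p=p)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(x, y=None, kind: str = "t"):
    """Two-sided group comparison.

    ``kind="t"``: Student's t-test (equal variances) between samples ``x``
    and ``y``.  ``kind="fisher"``: Fisher's exact test on the 2×2 table
    ``x`` (probability-ordering two-sided p).  Returns (statistic, p).
    """
    if kind == "t":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise StatisticsError("t-test needs n ≥ 2 per group")
        res = stats.ttest_ind(x, y, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher":
        table = np.asarray(x)
        if table.shape != (2, 2) or np.any(table < 0) or not np.issubdtype(
                table.dtype, np.integer):
            raise StatisticsError("Fisher test needs a 2×2 table of "
                                  "nonnegative integers")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"kind must be 't' or 'fisher', got {kind!r}")


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

_METRICS = ("delta_la", "delta_pv_mean", "n_pv_no_increase")


@dataclass
class CohortReport:
    """Results of the full statistics layer on one cohort table."""

    group_comparisons: pd.DataFrame
    univariate: pd.DataFrame
    multivariate: pd.DataFrame | None
    roc: dict                       # metric -> RocCurve
    survival: SurvivalFit | None
    warnings: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Cohort outcome statistics", "=" * 40, "",
                 "Group means by recurrence status (t-test)"]
        lines.append(self.group_comparisons.to_string(index=False))
        lines += ["", "Univariate logistic models (OR, 95% CI)"]
        lines.append(self.univariate.to_string(index=False))
        if self.multivariate is not None:
            lines += ["", "Multivariate logistic model (OR, 95% CI)"]
            lines.append(self.multivariate.to_string(index=False))
        lines += ["", "ROC AUC per metric"]
        for name, curve in self.roc.items():
            lines.append(f"  {name}: AUC = {curve.auc:.3f}")
        if self.survival is not None and self.survival.logrank_p is not None:
            lines += ["", f"Log-rank: chi2 = {self.survival.logrank_statistic:.3f}, "
                          f"p = {self.survival.logrank_p:.3f}"]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def _effects_frame(effects) -> pd.DataFrame:
    return pd.DataFrame([{
        "covariate": e.name, "odds_ratio": e.odds_ratio,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value,
    } for e in effects])


def analyze_cohort(df: pd.DataFrame, covariates=None) -> CohortReport:
    """Run the full statistics layer on a per-patient cohort table.

    Expects columns ``recurrence`` (0/1), ``followup_months``, ``event``
    (or recurrence reused as event flag), plus the fibrosis metrics
    ``delta_la``, ``delta_pv_mean``, ``n_pv_no_increase``.
    """
    warnings_ = []
    for col in ("recurrence", "followup_months"):
        if col not in df.columns:
            raise StatisticsError(f"cohort table lacks required column {col!r}")
    if np.any(df["followup_months"].to_numpy(dtype=float) <= 0):
        raise StatisticsError("follow-up times must be positive")
    y = df["recurrence"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise StatisticsError("single-class outcome; comparisons impossible")

    metrics = [m for m in _METRICS if m in df.columns]
    constant = [m for m in metrics
                if float(np.std(df[m].to_numpy(dtype=float))) == 0.0]
    for m in constant:
        warnings_.append(f"metric {m!r} is constant; excluded from models")
    rows = []
    for m in metrics:
        a = df.loc[df.recurrence == 1, m].to_numpy(dtype=float)
        b = df.loc[df.recurrence == 0, m].to_numpy(dtype=float)
        t, p = group_compare(a, b, kind="t")
        rows.append({"metric": m, "mean_recurrence": a.mean(),
                     "mean_no_recurrence": b.mean(), "t": t, "p_value": p})
    group_comparisons = pd.DataFrame(rows)

    covariates = list(covariates) if covariates else [
        m for m in metrics if m not in constant]
    uni_effects = []
    for cov in covariates:
        try:
            uni_effects.extend(logistic_fit(y, df[[cov]], mode="univariate"))
        except (SeparationError, StatisticsError) as exc:
            warnings_.append(f"univariate model for {cov!r} skipped: {exc}")
    uni = _effects_frame(uni_effects)
    multivariate = None
    if len(covariates) > 1:
        try:
            multivariate = _effects_frame(
                logistic_fit(y, df[covariates], mode="multivariate"))
        except (SeparationError, StatisticsError) as exc:
            warnings_.append(f"multivariate model skipped: {exc}")

    roc = {m: roc_auc(df[m].to_numpy(dtype=float), y) for m in metrics
           if m not in constant}

    survival = None
    if "n_pv_no_increase" in df.columns:
        strata = (df["n_pv_no_increase"].to_numpy(dtype=float) >= 1).astype(int)
        events = (df["event"] if "event" in df.columns else df["recurrence"])
        try:
            survival = km_logrank(df["followup_months"].to_numpy(dtype=float),
                                  events.to_numpy(dtype=int), strata)
        except StatisticsError as exc:
            warnings_.append(f"survival analysis skipped: {exc}")

    return CohortReport(group_comparisons=group_comparisons, univariate=uni,
                        multivariate=multivariate, roc=roc, survival=survival,
                        warnings=warnings_)
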