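"""Survival, contingency, group-comparison and drug-response statistics.

Thin, contract-checked wrappers over lifelines (Kaplan-Meier, log-rank,
Cox), scipy (chi-square with Yates correction, Fisher exact, Pearson) and
statsmodels (Tukey HSD), plus the drug-sensitivity screen rule: a drug is
differential between subgroups when its raw-AUC fold change exceeds 1.5
(either direction) and the Welch p-value on per-drug standardized AUC is
below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ContingencyResult",
    "SurvivalResult",
    "km_logrank",
    "cox_multivariate",
    "contingency_test",
    "anova_tukey",
    "correlate",
    "drug_response_compare",
]


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float
    p: float
    method: str


@dataclass
class SurvivalResult:
    """Per-group KM curves plus the log-rank test."""

    curves: Dict[str, pd.DataFrame]  # group -> (time, at_risk, survival)
    statistic: float
    p: float
    cox: Optional[pd.DataFrame] = None


def km_logrank(time: Sequence[float], event: Sequence[int],
               group: Sequence[str]) -> SurvivalResult:
    """Kaplan-Meier curves per group and the (k-1)-df log-rank test."""
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": np.asarray(group)})
    if df.groupby("group")["event"].sum().eq(0).all():
        raise ValueError("every group is fully censored; log-rank undefined")
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        curves[g] = pd.DataFrame({
            "time": tab.index.to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        })
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return SurvivalResult(curves=curves, statistic=float(res.test_statistic),
                          p=float(res.p_value))


def cox_multivariate(covariates: pd.DataFrame, time: pd.Series,
                     event: pd.Series) -> pd.DataFrame:
    """Multivariate Cox proportional hazards (Efron ties, Wald CIs).

    Returns one row per covariate: ``coef``, ``hr``, ``hr_lower``,
    ``hr_upper``, ``p``.
    """
    if (covariates.nunique() <= 1).any():
        bad = list(covariates.columns[covariates.nunique() <= 1])
        raise ValueError(f"constant covariates: {bad}")
    n_events = int(np.asarray(event).sum())
    if n_events < 5 * covariates.shape[1]:
        warnings.warn(f"only {n_events} events for {covariates.shape[1]} "
                      "covariates; estimates may be unstable")
    df = covariates.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    return pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "hr_lower": s["exp(coef) lower 95%"],
        "hr_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })


def contingency_test(a: int, b: int, c: int, d: int,
                     method: str = "chi2_yates") -> ContingencyResult:
    """2x2 association test on the table [[a, b], [c, d]].

    Default is the chi-square test with Yates continuity correction;
    ``method='fisher'`` gives the two-sided Fisher exact test.  A zero
    margin makes the chi-square undefined and raises with a suggestion to
    use Fisher.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if method == "chi2_yates":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("zero margin: chi-square undefined; use method='fisher'")
        res = sps.chi2_contingency(table, correction=True)
        return ContingencyResult(table, float(res.statistic), float(res.pvalue),
                                 "chi2_yates")
    if method == "fisher":
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return ContingencyResult(table, float(odds), float(p), "fisher")
    raise ValueError(f"unknown method {method!r}")


def anova_tukey(values: Sequence[float],
                groups: Sequence[str]) -> Tuple[float, pd.DataFrame]:
    """One-way ANOVA F-test plus Tukey HSD pairwise adjusted p-values.

    Returns (overall p, frame with group1/group2/meandiff/p_adj).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 3:
        raise ValueError("need at least 3 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    F, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(tk.summary().data[1:],
                         columns=[str(c) for c in tk.summary().data[0]])
    out = frame[["group1", "group2", "meandiff", "p-adj"]].rename(
        columns={"p-adj": "p_adj"})
    out[["meandiff", "p_adj"]] = out[["meandiff", "p_adj"]].astype(float)
    return float(p), out


def correlate(x: Sequence[float], y: Sequence[float],
              method: str = "pearson") -> Tuple[float, float]:
    """Correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def drug_response_compare(auc: pd.DataFrame, groups: pd.Series,
                          fc_min: float = 1.5,
                          p_max: float = 0.05) -> pd.DataFrame:
    """Differential ex vivo drug response between two subgroups.

    Per drug: fold change is the ratio of group means of raw AUC
    (group1 / group2, groups in sorted label order); the p-value is a
    Welch test on the per-drug z-scored AUC.  Drugs with fewer than 3
    non-missing samples in a group are skipped with a warning.  Returns
    the drugs with FC > fc_min or FC < 1/fc_min and p < p_max; direction
    is ``resistant`` when group1's mean AUC is higher (higher AUC = more
    resistant ex vivo), else ``sensitive``.
    """
    groups = groups.reindex(auc.index).dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    rows = []
    for drug in auc.columns:
        v = auc.loc[groups.index, drug]
        g1 = v[groups == labels[0]].dropna()
        g2 = v[groups == labels[1]].dropna()
        if len(g1) < 3 or len(g2) < 3:
            warnings.warn(f"drug {drug!r}: fewer than 3 samples in a group; skipped")
            continue
        z = (v - v.mean()) / v.std()
        _, p = sps.ttest_ind(z[groups == labels[0]].dropna(),
                             z[groups == labels[1]].dropna(), equal_var=False)
        fc = g1.mean() / g2.mean() if g2.mean() != 0 else np.inf
        hit = (fc > fc_min or fc < 1 / fc_min) and p < p_max
        if hit:
            rows.append({
                "drug": drug,
                "fold_change": fc,
                "p": float(p),
                "direction": "resistant" if g1.mean() > g2.mean() else "sensitive",
            })
    return pd.DataFrame(rows, columns=["drug", "fold_change", "p", "direction"])
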