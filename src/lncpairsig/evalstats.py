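"""Downstream evaluation of the risk stratification.

Kaplan-Meier curves and the log-rank test for survival differences,
chi-square tests of the risk group against clinicopathological
categories, rank-sum comparisons of risk scores and of IC50 values,
univariate/multivariate independence Cox models, and Spearman
correlation of the risk score with immune-infiltration fractions.

Note on nomenclature: comparisons between the two *independent* risk
groups use the two-sample Wilcoxon rank-sum (Mann-Whitney) test; a
signed-rank test would require paired observations, which do not exist
in this design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .ingest import ValidationError
from .sigfit import CoxModel, fit_cox


@dataclass
class KmCurve:
    """Product-limit survival curve over the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    group: str | None = None


@dataclass
class AssocResult:
    test: str
    statistic: float
    p: float
    effect: dict = field(default_factory=dict)
    group_sizes: tuple = ()


def km_estimate(times, events, group: str | None = None) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events precede censorings (the standard convention:
    a subject censored at t is still at risk for an event at t).
    Survival values are reported at the distinct event times only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ev_t = t[e == 1]
    uniq, d = np.unique(ev_t, return_counts=True)
    n = t.size
    at_risk = n - np.searchsorted(t, uniq, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(uniq, surv, at_risk, d, group)


def km_survival_at(times, events, horizon: float) -> float:
    """S(horizon) from the product-limit curve (1.0 before the first event)."""
    curve = km_estimate(times, events)
    mask = curve.times <= horizon
    if not mask.any():
        return 1.0
    return float(curve.survival[mask][-1])


def logrank_test(times, events, groups) -> AssocResult:
    """Two-group log-rank test (1 df, hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {labels.size}")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    med = {
        str(lab): float(np.median(times[groups == lab])) for lab in labels
    }
    return AssocResult(
        test="logrank",
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        effect={"median_followup": med},
        group_sizes=(int(a.sum()), int((~a).sum())),
    )


def chisq_association(group_labels, categories) -> AssocResult:
    """Pearson chi-square (no continuity correction) on the contingency table."""
    tab = pd.crosstab(pd.Series(group_labels), pd.Series(categories))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("contingency table needs at least 2 rows and 2 columns")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValidationError("degenerate contingency table (zero margin)")
    chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected count < 5 in at least one cell")
    return AssocResult(
        test="chisq",
        statistic=float(chi2),
        p=float(p),
        effect={"dof": int(dof)},
        group_sizes=tuple(int(x) for x in tab.sum(axis=1)),
    )


def ranksum_compare(values, groups) -> AssocResult:
    """Two-sample Wilcoxon rank-sum test, tie-corrected normal approximation."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError(f"rank-sum compares exactly 2 groups, got {labels.size}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group in rank-sum comparison")
    if np.ptp(values) == 0:
        stat, p = a.size * b.size / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return AssocResult(
        test="ranksum",
        statistic=stat,
        p=p,
        effect={
            "median": {str(labels[0]): float(np.median(a)), str(labels[1]): float(np.median(b))},
            "direction": str(labels[0]) if np.median(a) > np.median(b) else str(labels[1]),
        },
        group_sizes=(a.size, b.size),
    )


def independence_cox(
    covariates: pd.DataFrame, times, events
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and multivariate Cox models over clinical covariates + risk.

    ``covariates`` is samples x covariates, numerically coded (ordinal
    stages, age in years, risk score continuous).  Collinear covariates
    are dropped from the multivariate fit (later-listed column dropped),
    with a warning.  Returns forest-plot-ready tables.
    """
    rows = []
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)[:, None]
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name} is constant; skipped")
            continue
        m = fit_cox(times, events, x, names=[name])
        rows.append(m.summary())
    uni = pd.concat(rows) if rows else pd.DataFrame()

    keep = [c for c in covariates.columns if np.ptp(covariates[c].to_numpy(dtype=float)) > 0]
    X = covariates[keep].to_numpy(dtype=float)
    # drop later-listed collinear columns
    while len(keep) > 1 and np.linalg.matrix_rank(X - X.mean(axis=0)) < len(keep):
        warnings.warn(f"collinear covariate {keep[-1]} dropped from multivariate model")
        keep = keep[:-1]
        X = covariates[keep].to_numpy(dtype=float)
    multi = fit_cox(times, events, X, names=keep).summary()
    return uni, multi


def immune_correlation(
    risk: pd.Series, fractions: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Spearman correlation of the risk score with immune-cell fractions.

    Per cell type: Spearman rho (average-rank ties) with two-sided p (t
    approximation), plus a rank-sum comparison between the high/low risk
    groups when ``groups`` is given.  Constant columns are skipped.
    Rows are sorted by rho.
    """
    shared = risk.index.intersection(fractions.index)
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples")
    r = risk.loc[shared].to_numpy(dtype=float)
    rows = []
    for cell in fractions.columns:
        y = fractions.loc[shared, cell].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"constant immune fraction column {cell}; skipped")
            continue
        rho, p = stats.spearmanr(r, y)
        rec = {"cell_type": cell, "rho": float(rho), "p": float(p), "n": len(shared)}
        if groups is not None:
            g = groups.loc[shared]
            rs = ranksum_compare(y, g.to_numpy())
            rec["ranksum_p"] = rs.p
            rec["higher_in"] = rs.effect["direction"]
        rows.append(rec)
    if not rows:
        cols = ["rho", "p", "n"] + (["ranksum_p", "higher_in"] if groups is not None else [])
        return pd.DataFrame(columns=cols, index=pd.Index([], name="cell_type"))
    return pd.DataFrame(rows).set_index("cell_type").sort_values("rho")


def drug_sensitivity_compare(groups: pd.Series, ic50: pd.DataFrame) -> pd.DataFrame:
    """Per-drug rank-sum comparison of IC50 between high/low risk groups.

    Lower IC50 means greater sensitivity; ``lower_ic50_in`` names the
    group with the lower median.  Drug columns that are entirely missing
    are skipped.
    """
    shared = groups.index.intersection(ic50.index)
    g = groups.loc[shared]
    rows = []
    for drug in ic50.columns:
        y = ic50.loc[shared, drug]
        ok = y.notna()
        if not ok.any():
            warnings.warn(f"drug {drug} has no IC50 values; skipped")
            continue
        yv = y[ok].to_numpy(dtype=float)
        gv = g[ok].to_numpy()
        labels, counts = np.unique(gv, return_counts=True)
        if labels.size != 2 or counts.min() < 2:
            raise ValidationError(f"drug {drug}: both risk groups need >= 2 samples")
        rs = ranksum_compare(yv, gv)
        med = rs.effect["median"]
        lower = min(med, key=med.get)
        rows.append(
            {
                "drug": drug,
                "statistic": rs.statistic,
                "p": rs.p,
                "lower_ic50_in": lower,
                **{f"median_{k}": v for k, v in med.items()},
            }
        )
    return pd.DataFrame(rows).set_index("drug").sort_values("p")
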