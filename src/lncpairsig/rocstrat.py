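"""Time-dependent ROC analysis and risk-group stratification.

Cumulative-case / dynamic-control ROC at a horizon t: cases are subjects
with an observed event by t, controls those still event-free after t.
Censoring before t is handled with the Kaplan-Meier estimator: for a
marker X and threshold c,

    sensitivity(c) = [1 - S(t | X > c)] * P(X > c) / [1 - S(t)]
    specificity(c) = S(t | X <= c) * P(X <= c) / S(t)

with the conditional survival curves estimated by the product-limit
method inside the marker strata.  This parameter-free estimator can be
locally non-monotone in c; the raw curves are monotonized by cumulative
maximum before the trapezoidal AUC is taken.

The risk cut-off is Youden-style: the threshold on the 5-year curve that
maximizes sensitivity + specificity, ties broken toward the smaller
cut-off (the larger high-risk group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evalstats import km_survival_at
from .ingest import ValidationError

YEAR_DAYS = 365.0
HORIZONS = {"1y": 365.0, "3y": 1095.0, "5y": 1825.0}


@dataclass
class TdRocCurve:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class CutoffChoice:
    cutoff: float
    objective: float  # sensitivity + specificity at the cutoff
    horizon: float


def td_roc(risk, times, events, horizon: float) -> TdRocCurve:
    """Time-dependent ROC curve of a marker at a horizon (days)."""
    x = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    if not np.any((times <= horizon) & (events == 1)):
        raise ValidationError("no events before the horizon")

    s_t = km_survival_at(times, events, horizon)
    if s_t <= 0.0 or s_t >= 1.0:
        raise ValidationError(
            f"degenerate marginal survival S(t)={s_t}; ROC at this horizon is undefined"
        )

    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    n = x.size
    for i, c in enumerate(thresholds):
        hi = x > c
        p_hi = hi.mean()
        if p_hi == 0:
            sens[i] = 0.0
        else:
            s_hi = km_survival_at(times[hi], events[hi], horizon)
            sens[i] = (1.0 - s_hi) * p_hi / (1.0 - s_t)
        if p_hi == 1.0:
            spec[i] = 0.0
        else:
            s_lo = km_survival_at(times[~hi], events[~hi], horizon)
            spec[i] = s_lo * (1.0 - p_hi) / s_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # monotonize: sensitivity non-increasing, specificity non-decreasing in c
    sens = np.maximum.accumulate(sens[::-1])[::-1]
    spec = np.maximum.accumulate(spec)

    # traverse thresholds from largest to smallest so both coordinates are
    # non-decreasing (a proper ROC polyline), then trapezoid
    fpr = (1.0 - spec)[::-1]
    tpr = sens[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return TdRocCurve(horizon, thresholds, sens, spec, auc)


def choose_cutoff(curve: TdRocCurve) -> CutoffChoice:
    """Threshold maximizing sensitivity + specificity on the curve.

    Ties break toward the smaller cut-off (larger high-risk group).
    """
    if curve.thresholds.size < 2:
        raise ValidationError("curve must carry at least 2 thresholds")
    obj = curve.sensitivity + curve.specificity
    if np.ptp(obj) == 0:
        warnings.warn("all thresholds give the same objective; taking the first")
        best = 0
    else:
        best = int(np.argmax(obj))  # argmax takes the first = smallest threshold on ties
    return CutoffChoice(float(curve.thresholds[best]), float(obj[best]), curve.horizon)


def assign_groups(risk: pd.Series, cutoff: float) -> pd.Series:
    """Label samples high (risk > cutoff, strict) or low."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    groups = pd.Series(
        np.where(risk.to_numpy(dtype=float) > cutoff, "high", "low"),
        index=risk.index,
        name="risk_group",
    )
    counts = groups.value_counts()
    if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
        raise ValidationError("cutoff leaves one risk group empty")
    return groups


ORDINAL_CODES = {
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
    "T": {"T1": 1, "T2": 2, "T3": 3, "T4": 4},
    "M": {"M0": 0, "M1": 1},
    "N": {"N0": 0, "N1": 1, "N2": 2},
}


def encode_clinical_ordinal(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of clinical covariates for ROC/Cox comparisons.

    Stage I-IV -> 1-4, T1-T4 -> 1-4, M0/M1 -> 0/1, N0-N2 -> 0-2; age kept
    in years.  Already-numeric columns pass through unchanged.
    """
    out = pd.DataFrame(index=clinical.index)
    if "age" in clinical:
        out["age"] = clinical["age"].astype(float)
    for col, codes in ORDINAL_CODES.items():
        if col in clinical:
            vals = clinical[col]
            if pd.api.types.is_numeric_dtype(vals):
                out[col] = vals.astype(float)
            else:
                out[col] = vals.map(codes).astype(float)
    return out


def compare_clinical_roc(
    risk: pd.Series, clinical_num: pd.DataFrame, times, events, horizon: float = HORIZONS["5y"]
) -> pd.DataFrame:
    """AUC of the risk score vs each clinical covariate used as a marker."""
    markers = {"risk_score": risk.to_numpy(dtype=float)}
    for col in clinical_num.columns:
        v = clinical_num[col].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            warnings.warn(f"covariate {col} has a single level; skipped")
            continue
        markers[col] = v
    rows = [
        (name, td_roc(v, times, events, horizon).auc) for name, v in markers.items()
    ]
    return (
        pd.DataFrame(rows, columns=["marker", "auc"])
        .set_index("marker")
        .sort_values("auc", ascending=False)
    )
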