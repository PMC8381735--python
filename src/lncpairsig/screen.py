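"""Immune-related lncRNA screening.

Two sequential screens:

1. co-expression — a lncRNA is immune-related (irlncRNA) when its Pearson
   correlation with at least one immune protein-coding gene exceeds 0.4 at
   p < 0.001 (two-sided t test on the correlation);
2. differential expression — an irlncRNA is differentially expressed
   (DEirlncRNA) when |log2 fold change| between tumor and normal exceeds 1
   at a Benjamini-Hochberg FDR below 0.05.

Both screens operate on log2(FPKM + 1).  The correlation cut is signed
(r > 0.4, not |r|), and no multiplicity correction is applied to the
correlation p-values; the DE p-value is a two-sample Wilcoxon rank-sum
test with tie-corrected normal approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ExpressionMatrix, ValidationError

R_MIN = 0.4
P_MAX = 1e-3
LFC_MIN = 1.0
FDR_MAX = 0.05


def log2p1(x):
    """log2(x + 1), the conventional transform for FPKM-scale values."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided p from t = r * sqrt((n-2) / (1-r^2)), n-2 df
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def coexpression_screen(
    lnc_expr: ExpressionMatrix,
    immune_expr: ExpressionMatrix,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Screen lncRNAs for co-expression with any immune gene.

    Returns one row per lncRNA with its best (highest-r) immune partner,
    that partner's r and p, and a ``passed`` flag which is true when ANY
    immune partner satisfies r > r_min and p < p_max.  Zero-variance
    genes yield undefined correlations and are skipped as partners.
    """
    if not lnc_expr.sample_ids.equals(immune_expr.sample_ids):
        raise ValidationError("lncRNA and immune matrices must share the sample set and order")
    n = len(lnc_expr.sample_ids)
    if n < 3:
        raise ValidationError("need at least 3 shared samples for correlation")

    L = log2p1(lnc_expr.values.to_numpy())  # (n_lnc, n)
    M = log2p1(immune_expr.values.to_numpy())  # (n_imm, n)
    Ls = L - L.mean(axis=1, keepdims=True)
    Ms = M - M.mean(axis=1, keepdims=True)
    lsd = np.sqrt((Ls**2).sum(axis=1))
    msd = np.sqrt((Ms**2).sum(axis=1))
    lnc_ok = lsd > 0
    imm_ok = msd > 0

    R = np.full((L.shape[0], M.shape[0]), np.nan)
    if imm_ok.any() and lnc_ok.any():
        num = Ls[lnc_ok] @ Ms[imm_ok].T
        den = np.outer(lsd[lnc_ok], msd[imm_ok])
        R[np.ix_(lnc_ok, imm_ok)] = num / den
    P = _corr_pvalue(R, n)

    valid = ~np.isnan(R)
    pass_mat = valid & (R > r_min) & (P < p_max)
    rows = []
    imm_ids = immune_expr.gene_ids
    for i, g in enumerate(lnc_expr.gene_ids):
        if valid[i].any():
            j = int(np.nanargmax(R[i]))
            rows.append((g, imm_ids[j], R[i, j], P[i, j], bool(pass_mat[i].any())))
        else:
            rows.append((g, None, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["lnc_gene", "best_partner", "r", "p", "passed"]).set_index(
        "lnc_gene"
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    lnc_expr: ExpressionMatrix,
    lfc_min: float = LFC_MIN,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression of (ir)lncRNAs.

    log2fc is the difference of group means of log2(FPKM + 1); the raw p
    is a two-sided Wilcoxon rank-sum test on the same scale; FDR is
    Benjamini-Hochberg over all tested genes.
    """
    tum = lnc_expr.tumor_samples()
    nor = lnc_expr.normal_samples()
    if len(tum) < 2 or len(nor) < 2:
        raise ValidationError("need at least 2 tumor and 2 normal samples")
    Xt = log2p1(lnc_expr.values[tum].to_numpy())
    Xn = log2p1(lnc_expr.values[nor].to_numpy())
    log2fc = Xt.mean(axis=1) - Xn.mean(axis=1)
    p_raw = np.ones(len(log2fc))
    for i in range(Xt.shape[0]):
        if np.ptp(Xt[i]) == 0 and np.ptp(Xn[i]) == 0 and Xt[i][0] == Xn[i][0]:
            p_raw[i] = 1.0
            continue
        p_raw[i] = stats.mannwhitneyu(Xt[i], Xn[i], alternative="two-sided", method="asymptotic").pvalue
    fdr = bh_adjust(p_raw)
    passed = (np.abs(log2fc) > lfc_min) & (fdr < fdr_max)
    direction = np.where(log2fc > 0, "up", "down")
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "fdr": fdr,
            "direction": direction,
            "passed": passed,
        },
        index=lnc_expr.gene_ids,
    )
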