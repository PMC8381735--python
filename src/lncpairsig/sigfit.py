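"""Signature selection: Cox engine, univariate screen, LASSO, stepwise AIC.

The proportional-hazards engine maximizes the Efron-approximation partial
likelihood by Newton-Raphson with step-halving, so the log-likelihood is
non-decreasing across iterations.  Standard errors come from the inverse
observed information; per-covariate p-values are two-sided Wald.

Selection proceeds exactly as the signature-construction protocol
prescribes: a univariate Wald screen over all valid pairs (p < 0.05),
repeated k-fold cross-validated LASSO-Cox picking the penalty with the
smallest mean cross-validated partial-likelihood deviance, then an
AIC-minimizing stepwise refinement of the selected set (exhaustive
best-subset when the set is small enough to enumerate).  The risk score
of a sample is the dot product of its binary pair indicators with the
final multivariate coefficients.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ValidationError
from .pairenc import PairMatrix

BETA_BOUND = 20.0  # |beta| beyond this flags monotone-likelihood separation


@dataclass
class CoxModel:
    """A fitted proportional-hazards model (Efron ties)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    ties_method: str = "efron"

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return lo, hi

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "HR": self.hr,
                "HR_lower95": lo,
                "HR_upper95": hi,
                "p": self.p,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _validate_survival(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    if X.shape[0] != times.size:
        raise ValidationError("covariate matrix does not align with times")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event indicator must be binary")
    events = events.astype(np.int64)
    if events.sum() < 1:
        raise ValidationError("need at least one event")
    return times, events, X


def _efron_groups(t_sorted, e_sorted):
    """Start index and tied-event indices per unique event time."""
    ev_idx = np.flatnonzero(e_sorted)
    ev_t = t_sorted[ev_idx]
    uniq, first = np.unique(ev_t, return_index=True)
    bounds = np.append(first, ev_idx.size)
    groups = []
    for k in range(uniq.size):
        ids = ev_idx[bounds[k] : bounds[k + 1]]
        start = np.searchsorted(t_sorted, uniq[k], side="left")
        groups.append((start, ids))
    return groups


def _loglik_grad_hess(t, e, X, beta, groups, need_derivs=True):
    """Efron partial log-likelihood and derivatives at beta.

    ``t`` must be ascending; ``groups`` precomputed by _efron_groups.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()  # partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    if need_derivs:
        wxx = wx[:, :, None] * X[:, None, :]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))

    # singleton event times handled vectorized; tied groups looped
    single_starts, single_ids, tied = [], [], []
    for start, ids in groups:
        if ids.size == 1:
            single_starts.append(start)
            single_ids.append(ids[0])
        else:
            tied.append((start, ids))

    if single_ids:
        st = np.asarray(single_starts)
        ii = np.asarray(single_ids)
        s0 = S0[st]
        ll += eta[ii].sum() - np.log(s0).sum()
        if need_derivs:
            z = S1[st] / s0[:, None]
            g += X[ii].sum(axis=0) - z.sum(axis=0)
            H -= np.einsum("gij,g->ij", S2[st], 1.0 / s0) - z.T @ z

    for start, ids in tied:
        d = ids.size
        s0, s1 = S0[start], S1[start]
        s0d = w[ids].sum()
        s1d = wx[ids].sum(axis=0)
        ll += eta[ids].sum()
        if need_derivs:
            s2 = S2[start]
            s2d = wxx[ids].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = s0 - f * s0d
            ll -= np.log(phi)
            if need_derivs:
                z = (s1 - f * s1d) / phi
                g += -z
                H -= (s2 - f * s2d) / phi - np.outer(z, z)
        if need_derivs:
            g += X[ids].sum(axis=0)

    if need_derivs:
        return ll, g, H
    return ll


def cox_partial_loglik(times, events, X, beta) -> float:
    """Evaluate the Efron partial log-likelihood at a fixed beta."""
    times, events, X = _validate_survival(times, events, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    groups = _efron_groups(t, e)
    return _loglik_grad_hess(t, e, Xs, beta, groups, need_derivs=False)


def fit_cox(
    times,
    events,
    X,
    names=None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxModel:
    """Newton-Raphson fit of the Cox model with Efron tie handling.

    Convergence when the score's max absolute entry or the parameter
    change drops below ``tol``.  Step-halving guarantees a monotone
    log-likelihood; diverging coefficients (|beta| > 50, the signature
    of monotone-likelihood separation) are flagged as non-converged.
    """
    times, events, X = _validate_survival(times, events, X)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValidationError(f"constant covariate(s): {[names[i] for i in np.flatnonzero(const)]}")

    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    groups = _efron_groups(t, e)

    beta = np.zeros(p)
    ll, g, H = _loglik_grad_hess(t, e, Xs, beta, groups)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(-H + 1e-8 * np.eye(p), g)
        # step-halving: never accept a decrease in the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, H_new = _loglik_grad_hess(t, e, Xs, cand, groups)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        delta = cand - beta
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if np.abs(beta).max() > BETA_BOUND:
            worst = names[int(np.argmax(np.abs(beta)))]
            warnings.warn(f"possible separation: |beta| diverging for {worst}")
            break
        if np.abs(g).max() < tol or np.abs(delta).max() < tol:
            converged = True
            break
    if converged and np.abs(beta).max() > BETA_BOUND:
        # monotone likelihood: the score can vanish numerically while the
        # coefficient wanders off to infinity
        worst = names[int(np.argmax(np.abs(beta)))]
        warnings.warn(f"possible separation: |beta| diverging for {worst}")
        converged = False

    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxModel(
        names=names,
        beta=beta,
        se=se,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# selection pipeline


def univariate_screen(
    pm: PairMatrix, times, events, p_max: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """One single-covariate Cox fit per pair; retain Wald p < p_max.

    Returns the per-pair result table and the retained pair IDs.
    Non-converged pairs are excluded with a warning; zero retained pairs
    halt the pipeline with an explanatory error.
    """
    rows = []
    for pid, c in zip(pm.pair_ids, pm.C):
        x = c.astype(float)[:, None]
        try:
            m = fit_cox(times, events, x, names=[pid])
        except ValidationError:
            continue
        rows.append(
            (pid, m.beta[0], m.se[0], m.hr[0], m.ci95[0][0], m.ci95[1][0], m.p[0], m.converged)
        )
    res = pd.DataFrame(
        rows,
        columns=["pair", "beta", "se", "HR", "HR_lower95", "HR_upper95", "p", "converged"],
    ).set_index("pair")
    n_bad = int((~res["converged"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} pairs failed to converge and were excluded")
    retained = res.index[(res["p"] < p_max) & res["converged"]].tolist()
    if not retained:
        raise ValidationError(
            "univariate screen retained zero pairs; the cohort carries no "
            "detectable prognostic pair signal at this threshold"
        )
    return res, retained


def _cv_folds(n: int, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, n_folds)


def lasso_cox_select(
    pm: PairMatrix,
    times,
    events,
    n_folds: int = 10,
    n_repeats: int = 10,
    n_lambdas: int = 30,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Repeated cross-validated LASSO-Cox selection.

    Fits an L1-penalized Cox model over a log-spaced penalty path, then
    repeats k-fold cross-validation ``n_repeats`` times with reshuffled
    folds.  The cross-validation error is the Verweij-van-Houwelingen
    partial-likelihood deviance; the chosen penalty minimizes its mean
    over all folds and repeats, and the returned pairs are those with a
    nonzero coefficient at that penalty in the full-data fit.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    Xall = pm.C.T.astype(float)
    n = Xall.shape[0]
    y = Surv.from_arrays(event=events, time=times)

    n_events = int(events.sum())
    if n_events < n_folds:
        warnings.warn(f"only {n_events} events; reducing folds from {n_folds} to {max(2, n_events)}")
        n_folds = max(2, n_events)

    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=0.05, max_iter=100000
    )
    full.fit(Xall, y)
    alphas = full.alphas_

    rng = np.random.default_rng(seed)
    dev = np.zeros((n_repeats * n_folds, alphas.size))
    dev[:] = np.nan
    row = 0
    for _ in range(n_repeats):
        for fold in _cv_folds(n, n_folds, rng):
            train = np.setdiff1d(np.arange(n), fold)
            keep = np.ptp(Xall[train], axis=0) > 0
            mdl = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, max_iter=100000)
            try:
                mdl.fit(Xall[train][:, keep], y[train])
            except (ValueError, ArithmeticError):
                row += 1
                continue
            coefs = np.zeros((Xall.shape[1], len(mdl.alphas_)))
            coefs[keep] = mdl.coef_
            # Verweij & van Houwelingen: dev = -2 [ ll_all(beta) - ll_train(beta) ]
            for a in range(len(mdl.alphas_)):
                b = coefs[:, a]
                ll_all = cox_partial_loglik(times, events.astype(int), Xall, b)
                ll_tr = cox_partial_loglik(
                    times[train], events[train].astype(int), Xall[train], b
                )
                dev[row, a] = -2.0 * (ll_all - ll_tr)
            row += 1

    mean_dev = np.nanmean(dev, axis=0)
    n_nonzero_full = np.count_nonzero(full.coef_, axis=0)
    cv_table = pd.DataFrame(
        {"lambda": alphas, "mean_cv_deviance": mean_dev, "n_nonzero": n_nonzero_full}
    )
    best = int(np.nanargmin(mean_dev))
    selected = [pm.pair_ids[i] for i in np.flatnonzero(full.coef_[:, best])]
    if not selected:
        nz = np.flatnonzero(n_nonzero_full > 0)
        if nz.size == 0:
            raise ValidationError("LASSO selected no pairs at any penalty")
        warnings.warn("empty selection at the CV-optimal penalty; falling back to the "
                      "largest penalty selecting at least one pair")
        best = int(nz[0])  # alphas are descending: first nonzero = largest penalty
        selected = [pm.pair_ids[i] for i in np.flatnonzero(full.coef_[:, best])]
    return selected, cv_table


def stepwise_aic(
    pm: PairMatrix, times, events, exhaustive_max: int = 12
) -> CoxModel:
    """AIC-minimizing refinement of the LASSO-selected pair set.

    With ``k <= exhaustive_max`` covariates, all 2^k - 1 non-empty
    subsets are enumerated and the AIC-minimal model returned; otherwise
    backward elimination repeatedly drops the covariate whose removal
    most decreases AIC, stopping when no removal helps.
    """
    names = pm.pair_ids
    X = pm.C.T.astype(float)
    k = len(names)
    if k == 0:
        raise ValidationError("no pairs to refine")

    def _fit(cols):
        return fit_cox(times, events, X[:, cols], names=[names[c] for c in cols])

    if k <= exhaustive_max:
        best = None
        for r in range(1, k + 1):
            for cols in itertools.combinations(range(k), r):
                try:
                    m = _fit(list(cols))
                except ValidationError:
                    continue
                if not m.converged:
                    continue
                if best is None or m.aic < best.aic:
                    best = m
        if best is None:
            raise ValidationError("no subset model converged")
        return best

    cols = list(range(k))
    current = _fit(cols)
    while len(cols) > 1:
        best_drop, best_model = None, None
        for c in cols:
            reduced = [x for x in cols if x != c]
            try:
                m = _fit(reduced)
            except ValidationError:
                continue
            if not m.converged:
                warnings.warn(f"candidate refit without {names[c]} failed to converge; skipped")
                continue
            if m.aic < current.aic and (best_model is None or m.aic < best_model.aic):
                best_drop, best_model = c, m
        if best_drop is None:
            break
        cols.remove(best_drop)
        current = best_model
    return current


@dataclass
class Signature:
    """The deliverable: pair list, Cox weights, and the risk cut-off."""

    pairs: list[str]
    weights: np.ndarray
    cutoff: float | None = None
    horizon_days: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.pairs) < 1:
            raise ValidationError("a signature needs at least one pair")
        if not np.isfinite(self.weights).all():
            raise ValidationError("signature weights must be finite")

    @classmethod
    def from_model(cls, model: CoxModel, cutoff=None, horizon_days=None) -> "Signature":
        return cls(list(model.names), model.beta.copy(), cutoff, horizon_days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pair": self.pairs, "weight": self.weights}).set_index("pair")


def risk_scores(sig: Signature, pm: PairMatrix) -> pd.Series:
    """Risk score per sample: sum_i C_i * W_i over the signature pairs."""
    sub = pm.subset_pairs(sig.pairs)  # raises if a pair is missing
    scores = sig.weights @ sub.C.astype(float)
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")
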