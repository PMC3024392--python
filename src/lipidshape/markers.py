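"""Logistic DCM-risk marker model.

Candidate lipids (typically the between-study concordant species) are fed
into a logistic regression of case status; the subset is selected by
stepwise AIC, the classification threshold on the predicted probability is
tuned to minimise training misclassifications, and the frozen model is then
transferred to the independent study where a chi-square test on the 2x2
predicted-vs-true table and an ROC curve quantify generalisation.

The logistic likelihood is maximised by iteratively reweighted least
squares (IRLS == Newton-Raphson for this model); standard errors come from
the inverse observed information, z = estimate / SE, and two-sided normal
p-values. Quasi-complete separation makes coefficients diverge; it is
detected and flagged rather than silently reported, with an optional
ridge-stabilised refit for tooling that needs finite numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "LogisticModel",
    "TransferEvaluation",
    "fit_logistic",
    "stepwise_aic",
    "tune_threshold",
    "evaluate_transfer",
]


@dataclass
class LogisticModel:
    """Fitted logistic marker model."""

    variables: list[str]
    coef: np.ndarray              # aligned with variables
    intercept: float
    se: np.ndarray                # intercept first, then variables
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float
    loglik_trace: list[float]
    separation: bool = False
    threshold: float = 0.5

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise KeyError(f"predictor columns missing from data: {missing}")
        eta = self.intercept + X[self.variables].values @ self.coef
        return _sigmoid(eta)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def summary(self) -> pd.DataFrame:
        names = ["(Intercept)"] + list(self.variables)
        est = np.concatenate([[self.intercept], self.coef])
        return pd.DataFrame(
            {"estimate": est, "std_error": self.se, "z_value": self.z,
             "p_value": self.p},
            index=names,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"variables": list(self.variables),
                 "intercept": float(self.intercept),
                 "coefficients": [float(c) for c in self.coef],
                 "std_errors": [float(s) for s in self.se],
                 "threshold": float(self.threshold),
                 "aic": float(self.aic),
                 "separation": bool(self.separation)},
                fh, indent=1,
            )


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of binary ``y`` on the columns of
    ``X`` (intercept added internally).

    ``ridge`` adds a small L2 penalty to the Newton system only — use it to
    stabilise separated fits; 0 keeps the fit exactly ML.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    Xm = np.column_stack([np.ones(len(y))] + [X[c].values for c in X.columns])
    if X.shape[1] > 0:
        sds = Xm[:, 1:].std(axis=0)
        if np.any(sds == 0):
            j = int(np.argmax(sds == 0))
            raise ValueError(f"constant predictor: {X.columns[j]!r}")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    beta = np.zeros(Xm.shape[1])
    trace = [_loglik(y, Xm @ beta)]
    for _ in range(max_iter):
        eta = Xm @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        # Newton step with step-halving so the log-likelihood never decreases
        grad = Xm.T @ (y - mu) - ridge * beta
        info = (Xm * w[:, None]).T @ Xm + ridge * np.eye(len(beta))
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        ll_old = trace[-1]
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, Xm @ cand)
            if ll_new >= ll_old - 1e-14:
                break
            scale *= 0.5
        beta = beta + scale * step
        trace.append(_loglik(y, Xm @ beta))
        if abs(trace[-1] - ll_old) < tol * (abs(ll_old) + tol):
            break
    eta = Xm @ beta
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    info = (Xm * w[:, None]).T @ Xm
    separation = bool(np.max(np.abs(beta)) > 30.0 or np.min(w) < 1e-12)
    try:
        diag = np.diag(np.linalg.inv(info)).copy()
        with np.errstate(invalid="ignore"):
            se = np.sqrt(diag)
        bad = ~np.isfinite(se) | (se <= 0)
        if bad.any():
            se[bad] = np.inf
            separation = True
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.inf)
        separation = True
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ll = trace[-1]
    k = Xm.shape[1]
    return LogisticModel(
        variables=list(X.columns), coef=beta[1:], intercept=float(beta[0]),
        se=se, z=z, p=p, loglik=ll, aic=2.0 * k - 2.0 * ll,
        loglik_trace=trace, separation=separation,
    )


def stepwise_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    start: str = "full",
    max_steps: int = 100,
) -> LogisticModel:
    """Bidirectional stepwise subset selection minimising AIC = 2k - 2*loglik.

    Each step evaluates every single-variable drop from and add to the
    current subset and takes the move with the lowest AIC if it strictly
    improves; stops at a local minimum. ``start`` is ``"full"`` (backward-
    then-bidirectional, the default) or ``"empty"`` (forward-leaning).
    Deterministic: ties are broken by candidate order, drops before adds.
    """
    candidates = list(X.columns)
    if len(candidates) > 30:
        raise ValueError("stepwise search limited to <= 30 candidates")
    current = list(candidates) if start == "full" else []
    best = fit_logistic(X[current], y)
    for _ in range(max_steps):
        moves: list[tuple[float, list[str]]] = []
        for v in current:
            subset = [c for c in current if c != v]
            moves.append((fit_logistic(X[subset], y).aic, subset))
        for v in candidates:
            if v not in current:
                subset = current + [v]
                moves.append((fit_logistic(X[subset], y).aic, subset))
        if not moves:
            break
        best_aic, best_subset = min(moves, key=lambda m: m[0])
        if best_aic < best.aic - 1e-9:
            current = best_subset
            best = fit_logistic(X[current], y)
        else:
            break
    return best


def tune_threshold(model: LogisticModel, X: pd.DataFrame, y: np.ndarray) -> LogisticModel:
    """Pick the probability cutoff minimising training misclassifications.

    Candidates are the midpoints between consecutive distinct sorted
    predicted probabilities (plus the 0/1 guards); among minimisers the one
    closest to 0.5 wins. Returns a copy of the model with ``threshold`` set.
    """
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    uniq = np.unique(proba)
    if len(uniq) == 1:
        # degenerate: only all-positive / all-negative predictions exist;
        # 0.5 stays a candidate so balanced ties resolve there
        u = uniq[0]
        cands = np.array([u / 2.0, 0.5, (1.0 + u) / 2.0])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        cands = np.concatenate([[uniq[0] / 2.0], mids, [(1.0 + uniq[-1]) / 2.0]])
        cands = np.concatenate([cands, [0.5]])
    errs = np.array([np.sum((proba >= t).astype(int) != y) for t in cands])
    best = errs.min()
    ties = cands[errs == best]
    threshold = float(ties[np.argmin(np.abs(ties - 0.5))])
    out = LogisticModel(**{**model.__dict__})
    out.threshold = threshold
    return out


@dataclass
class TransferEvaluation:
    """Frozen-model performance on an independent cohort."""

    confusion: np.ndarray          # [[TN, FP], [FN, TP]], true in rows
    chi2: float
    chi2_p: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float

    @property
    def misclassifications(self) -> int:
        return int(self.confusion[0, 1] + self.confusion[1, 0])

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def evaluate_transfer(
    model: LogisticModel,
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    continuity_correction: bool = False,
) -> TransferEvaluation:
    """Apply a fitted model (coefficients and threshold frozen) to a new
    cohort: confusion matrix, 1-df chi-square on the predicted-vs-true 2x2
    table (no Yates correction by default), and an ROC curve with trapezoid
    area from the predicted probabilities."""
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    pred = (proba >= model.threshold).astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, q in zip(y, pred):
        confusion[t, q] += 1
    if np.any(confusion.sum(axis=0) == 0) or np.any(confusion.sum(axis=1) == 0):
        chi2, chi2_p = np.nan, np.nan  # degenerate margin: test undefined
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(
            confusion, correction=continuity_correction
        )
    fpr, tpr, _ = roc_curve(y, proba)
    auc = float(np.trapezoid(tpr, fpr))
    return TransferEvaluation(confusion=confusion, chi2=float(chi2),
                              chi2_p=float(chi2_p), roc_fpr=fpr, roc_tpr=tpr,
                              roc_auc=auc)
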