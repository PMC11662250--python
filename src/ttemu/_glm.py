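"""Weighted logistic-regression solver used by the propensity, censoring and
pooled hazard models.

A compact iteratively-reweighted-least-squares fit with step halving, optional
ridge stabilization and warm starts.  The bootstrap refits the propensity and
hazard models hundreds of times on a fixed design with varying frequency
weights, which is why the solver lives in-package; it is cross-checked against
statsmodels GLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EstimationError(RuntimeError):
    pass


def sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=np.float64)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class LogitFit:
    params: np.ndarray
    fitted: np.ndarray
    n_iter: int
    converged: bool
    deviance: float
    max_score: float
    separation: bool
    ridge: float = 0.0
    cov_params: np.ndarray | None = None


def _deviance(y, p, w):
    # binomial deviance, valid for fractional y
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    ll = np.where(np.isfinite(ll), ll, 0.0)
    return -2.0 * float(np.sum(w * ll))


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
    compute_cov: bool = False,
) -> LogitFit:
    """Weighted maximum-likelihood logistic regression via IRLS.

    ``y`` may be fractional (expected event fractions with ``weights`` acting
    as binomial totals).  On a singular or non-finite normal-equations step the
    fit retries once with a small ridge penalty and raises if that also fails.
    """

    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise EstimationError("negative weights")
    ybar = float(np.average(y, weights=w)) if n else 0.5
    if not (0.0 < ybar < 1.0):
        raise EstimationError(
            f"degenerate response: weighted event fraction {ybar:.4g}"
        )
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=np.float64).copy()
    eta = X @ beta
    p = sigmoid(eta)
    dev = _deviance(y, p, w) + ridge * float(beta @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wt = w * p * (1.0 - p)
        # clip curvature to keep the normal equations well-posed under
        # quasi-separation; the score still drives the update
        wt = np.maximum(wt, 1e-12)
        z = w * (y - p)
        xtwx = (X * wt[:, None]).T @ X
        score = X.T @ z - ridge * beta
        if ridge > 0.0:
            xtwx = xtwx + ridge * np.eye(k)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                return fit_logit(
                    X, y, weights, start=beta, ridge=1e-6, max_iter=max_iter,
                    tol=tol, compute_cov=compute_cov,
                )
            raise EstimationError("singular information matrix")
        if not np.all(np.isfinite(step)):
            raise EstimationError("non-finite IRLS step")
        # step halving on deviance increase
        lam = 1.0
        for _ in range(30):
            beta_new = beta + lam * step
            p_new = sigmoid(X @ beta_new)
            dev_new = _deviance(y, p_new, w) + ridge * float(beta_new @ beta_new)
            if dev_new <= dev + 1e-12:
                break
            lam *= 0.5
        beta, p = beta_new, p_new
        delta = abs(dev - dev_new)
        dev = dev_new
        if delta < tol * (abs(dev) + 1.0):
            converged = True
            break
    max_score = float(np.max(np.abs(X.T @ (w * (y - p)) - ridge * beta))) if k else 0.0
    separation = bool(np.any((p < 1e-8) | (p > 1 - 1e-8)))
    cov = None
    if compute_cov:
        wt = np.maximum(w * p * (1.0 - p), 1e-12)
        info = (X * wt[:, None]).T @ X + ridge * np.eye(k)
        cov = np.linalg.pinv(info)
    return LogitFit(
        params=beta, fitted=p, n_iter=it, converged=converged,
        deviance=float(dev), max_score=max_score, separation=separation,
        ridge=ridge, cov_params=cov,
    )


@dataclass
class DesignInfo:
    """Frozen design-matrix recipe so bootstrap refits reuse identical columns."""

    columns: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)
    dropped_collinear: list[str] = field(default_factory=list)


def prune_design(X: np.ndarray, names: list[str], weights=None):
    """Drop constant then collinear columns (rank-revealing QR); keeps order.

    Returns (X_pruned, kept_index, DesignInfo).  The intercept (a column named
    'const') is always retained.
    """

    X = np.asarray(X, dtype=np.float64)
    n, k = X.shape
    keep = []
    dropped_const = []
    for j in range(k):
        col = X[:, j]
        if names[j] != "const" and np.all(col == col[0]):
            dropped_const.append(names[j])
        else:
            keep.append(j)
    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]
    dropped_coll: list[str] = []
    if Xk.shape[1] > 1:
        from scipy.linalg import qr

        scale = np.sqrt(np.mean(Xk * Xk, axis=0))
        scale[scale == 0] = 1.0
        _, r, piv = qr(Xk / scale, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag[0] * max(n, Xk.shape[1]) * np.finfo(float).eps * 100
        rank = int(np.sum(diag > tol))
        if rank < Xk.shape[1]:
            drop_pos = sorted(piv[rank:])
            dropped_coll = [kept_names[j] for j in drop_pos]
            mask = np.ones(Xk.shape[1], dtype=bool)
            mask[drop_pos] = False
            Xk = Xk[:, mask]
            kept_names = [nm for nm, m in zip(kept_names, mask) if m]
    info = DesignInfo(
        columns=kept_names,
        dropped_constant=dropped_const,
        dropped_collinear=dropped_coll,
    )
    return np.ascontiguousarray(Xk), kept_names, info
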