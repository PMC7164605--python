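"""Internal estimation primitives.

All mean models in the pipeline are either Gaussian with an independence
working structure (point estimates identical to weighted least squares) or
weighted logistic regressions; inference everywhere is by cluster bootstrap,
so only point estimates and residual scales are needed.  These primitives are
plain numpy so they stay cheap inside bootstrap-within-replicate simulation
loops; tests cross-check them against statsmodels GEE/GLM.
"""

from __future__ import annotations

import numpy as np


class FitError(RuntimeError):
    """A model fit failed (rank deficiency, separation, non-convergence)."""


def drop_constant_columns(X: np.ndarray, protect: np.ndarray | None = None):
    """Mask of columns with any variation (constant non-intercept columns in
    a subsample carry no information and break the design's rank).

    ``protect`` marks columns kept regardless (e.g. the intercept / a
    constant-spanning spline block, identified by the caller).
    """
    ptp = X.max(axis=0) - X.min(axis=0)
    keep = ptp > 0
    if protect is not None:
        keep |= protect
    if not keep.any():
        raise FitError("design has no varying columns")
    return keep


def wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted least squares.

    Returns
    -------
    beta : (p,) coefficients
    resid_sd : residual standard deviation, sqrt(sum w * r^2 / (sum w - p))
        with w normalized to mean 1 (so unweighted reduces to the usual
        sqrt(RSS / (n - p))).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if w is None:
        Xw, yw = X, y
        wn = np.ones(n)
    else:
        wn = np.asarray(w, dtype=float)
        wn = wn * (n / wn.sum())
        sw = np.sqrt(wn)
        Xw, yw = X * sw[:, None], y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise FitError(f"rank-deficient design: rank {rank} < {p} columns")
    resid = y - X @ beta
    dof = max(n - p, 1)
    resid_sd = float(np.sqrt(np.sum(wn * resid**2) / dof))
    return beta, resid_sd


def _neg_loglik_logit(X, y, wn, beta):
    eta = np.clip(X @ beta, -700, 700)
    return float(np.sum(wn * (np.logaddexp(0.0, eta) - y * eta)))


def irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> np.ndarray:
    """Weighted logistic regression by iteratively reweighted least squares
    with deviance-guarded step halving.

    ``w`` are prior (frequency-type) weights.  Raises FitError on apparent
    separation (diverging coefficients) or non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.sum() == 0:
        raise FitError("no events in risk set")
    if y.sum() == n:
        raise FitError("all records are events; logistic fit degenerate")
    wn = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(p)
    nll = _neg_loglik_logit(X, y, wn, beta)
    for it in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = np.maximum(wn * mu * (1 - mu), 1e-12)
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-12)
        swt = np.sqrt(wt)
        try:
            prop, _, rank, _ = np.linalg.lstsq(X * swt[:, None], z * swt, rcond=None)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise FitError(f"IRLS linear algebra failure: {e}") from e
        if rank < p:
            raise FitError(f"rank-deficient design in logistic fit: rank {rank} < {p}")
        # step halving keeps heavy bootstrap weights from oscillating
        step = prop - beta
        nll_new = _neg_loglik_logit(X, y, wn, prop)
        halvings = 0
        while nll_new > nll + 1e-10 and halvings < 12:
            step *= 0.5
            prop = beta + step
            nll_new = _neg_loglik_logit(X, y, wn, prop)
            halvings += 1
        delta = np.max(np.abs(step))
        beta = prop
        if np.max(np.abs(beta)) > 1e4:
            raise FitError("logistic coefficients diverging; possible separation")
        if delta < tol * (1.0 + np.max(np.abs(beta))) or abs(nll - nll_new) < 1e-12 * (1 + abs(nll)):
            return beta
        nll = nll_new
    raise FitError(f"logistic IRLS did not converge in {max_iter} iterations")


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)
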