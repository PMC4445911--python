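"""Phylogenetic generalized least squares with ML estimation of Pagel's lambda.

The model is

    y = X beta + eps,    eps ~ N(0, sigma^2 * V(lambda))

where V(lambda) is the phylogenetic variance-covariance matrix with its
off-diagonal entries scaled by lambda in [0, 1].  For a fixed lambda, beta
and sigma^2 have closed-form ML estimates, so lambda is found by bounded
one-dimensional maximization of the profile log-likelihood

    l(lambda) = -1/2 [ n ln(2 pi) + n ln(RSS_W / n) + ln det W + n ],

with W = V(lambda) and RSS_W the residual sum of squares in the
W-whitened metric.  All linear algebra goes through a Cholesky whitening
of W; no explicit matrix inverse is ever formed.

t statistics use the unbiased residual variance RSS_W / (n - k) with
df = n - k, matching the usual GLS output.  AICc counts every estimated
quantity: the k regression coefficients plus sigma^2 plus lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from .phylo import VCV, lambda_transform

__all__ = ["PGLSFit", "gls_solve", "loglik_given_lambda", "fit_pgls", "aicc"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient at column {column!r}")


@dataclass
class GLSSolution:
    beta: np.ndarray
    se: np.ndarray
    rss: float            # residual sum of squares in the V-metric
    resid_whitened: np.ndarray
    logdet: float         # ln det V
    XtVinvX_inv: np.ndarray


@dataclass
class PGLSFit:
    """A fitted PGLS model: coefficients and the statistics reported with it."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lambda_hat: float
    sigma2_hat: float     # ML estimate RSS/n
    loglik: float
    r2: float
    adj_r2: float
    F: float
    F_df: tuple[int, int]
    F_p: float
    aicc: float
    n: int
    k: int                # number of regression coefficients
    K: int                # parameters counted by AICc: k + sigma^2 + lambda
    rss: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-coefficient summary."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "lambda": self.lambda_hat,
                "n": self.n,
                "aicc": self.aicc,
            }
        )

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])


def _whiten(V: np.ndarray) -> np.ndarray:
    """Cholesky factor L of V (lower); raises if V is not positive definite."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance matrix is not positive definite: {exc}"
        ) from exc


def gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray,
              columns: list[str] | None = None) -> GLSSolution:
    """Solve the GLS normal equations via Cholesky whitening.

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y, computed as the OLS solution of
    the whitened system L^-1 y = L^-1 X beta with V = L L'.  Standard
    errors use the unbiased residual variance RSS/(n-k).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different numbers of rows")
    L = _whiten(np.asarray(V, dtype=float))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    Q, R = np.linalg.qr(Xw)
    rdiag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (rdiag.max() if rdiag.size else 0.0)
    bad = np.nonzero(rdiag <= tol)[0]
    if bad.size:
        name = columns[bad[0]] if columns else f"column {bad[0]}"
        raise RankDeficientError(str(name))
    beta = linalg.solve_triangular(R, Q.T @ yw, lower=False)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    Rinv = linalg.solve_triangular(R, np.eye(k), lower=False)
    XtVinvX_inv = Rinv @ Rinv.T
    sigma2_unb = rss / (n - k) if n > k else np.nan
    se = np.sqrt(np.maximum(sigma2_unb * np.diag(XtVinvX_inv), 0.0))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return GLSSolution(beta, se, rss, resid, logdet, XtVinvX_inv)


def loglik_given_lambda(y: np.ndarray, X: np.ndarray, V: np.ndarray,
                        lam: float) -> float:
    """Profile log-likelihood of lambda, with beta and sigma^2 maximized out."""
    W = lambda_transform(np.asarray(V, dtype=float), lam)
    sol = gls_solve(y, X, W)
    n = len(np.asarray(y).ravel())
    sigma2_ml = sol.rss / n
    if sigma2_ml <= 0:
        # perfect fit: likelihood diverges; return a large finite value
        return np.inf
    return -0.5 * (n * _LOG_2PI + n * np.log(sigma2_ml) + sol.logdet + n)


def _profile_lambda(y, X, V, grid_size: int = 21, xatol: float = 1e-6):
    """Maximize the profile likelihood over lambda in [0, 1].

    A coarse grid pre-scan guards against local maxima near the
    boundaries; the bracketed bounded search then refines to ``xatol``.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    ll = np.array([loglik_given_lambda(y, X, V, g) for g in grid])
    if not np.all(np.isfinite(ll)):
        finite = np.isfinite(ll)
        if not finite.any():
            raise RuntimeError("profile likelihood non-finite on the whole grid")
        # +inf means a perfect fit at that lambda; take it directly
        if np.isposinf(ll).any():
            i = int(np.argmax(np.isposinf(ll)))
            return float(grid[i]), float(ll[i]), (grid, ll)
        grid, ll = grid[finite], ll[finite]
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi - lo < xatol:
        return float(grid[i]), float(ll[i]), (grid, ll)
    res = minimize_scalar(
        lambda lam: -loglik_given_lambda(y, X, V, float(np.clip(lam, 0, 1))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    lam_hat, ll_hat = float(np.clip(res.x, 0.0, 1.0)), -float(res.fun)
    # endpoint check: the bounded search can miss a maximum at 0 or 1
    for cand_lam, cand_ll in ((float(grid[i]), float(ll[i])),
                              (0.0, float(ll[0]) if grid[0] == 0 else None),
                              (1.0, float(ll[-1]) if grid[-1] == 1 else None)):
        if cand_ll is not None and cand_ll > ll_hat:
            lam_hat, ll_hat = cand_lam, cand_ll
    return lam_hat, ll_hat, (grid, ll)


def aicc(loglik: float, k_beta: int, n: int, extra_params: int = 2) -> float:
    """Small-sample corrected Akaike information criterion.

    K counts every estimated quantity: the ``k_beta`` regression
    coefficients plus, by default, sigma^2 and lambda (``extra_params=2``).
    """
    K = k_beta + extra_params
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for K={K}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_pgls(y: np.ndarray, X: np.ndarray, V: VCV | np.ndarray,
             terms: list[str] | None = None,
             lambda_grid: int = 21, xatol: float = 1e-6) -> PGLSFit:
    """Fit PGLS with lambda estimated by maximum likelihood.

    Parameters
    ----------
    y
        Response vector (aligned to the VCV tip order).
    X
        Design matrix including the intercept column.
    V
        Phylogenetic VCV (``VCV`` object or plain array), rows/cols
        aligned with ``y``.
    terms
        Column labels for ``X``; defaults to ``b0, b1, ...``.

    Notes
    -----
    r^2 is defined as 1 - RSS_W / TSS_W where TSS_W is the residual sum
    of squares of the intercept-only model in the same whitened metric
    (at the fitted lambda); this convention is recorded in ``meta``.
    """
    Vm = V.matrix if isinstance(V, VCV) else np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if terms is None:
        terms = [f"b{i}" for i in range(k)]
    if n <= k:
        raise ValueError(f"n={n} must exceed the number of coefficients k={k}")

    lam_hat, ll_hat, profile = _profile_lambda(y, X, Vm, lambda_grid, xatol)
    W = lambda_transform(Vm, lam_hat)
    sol = gls_solve(y, X, W, columns=terms)
    sigma2_ml = sol.rss / n

    dof = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(sol.se > 0, sol.beta / sol.se, np.inf * np.sign(sol.beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    # intercept-only fit in the same metric for TSS and the overall F
    ones = np.ones((n, 1))
    tss = gls_solve(y, ones, W).rss
    if tss > 0:
        r2 = 1.0 - sol.rss / tss
    else:
        r2 = 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    if k > 1 and sol.rss > 0:
        F = ((tss - sol.rss) / (k - 1)) / (sol.rss / dof)
        F_p = float(stats.f.sf(F, k - 1, dof))
    elif k > 1:
        F, F_p = np.inf, 0.0
    else:
        F, F_p = np.nan, np.nan

    if np.isinf(ll_hat):
        aicc_val = -np.inf
    else:
        aicc_val = aicc(ll_hat, k, n)

    return PGLSFit(
        terms=list(terms),
        beta=sol.beta,
        se=sol.se,
        t=tvals,
        p=pvals,
        lambda_hat=lam_hat,
        sigma2_hat=sigma2_ml,
        loglik=ll_hat,
        r2=float(r2),
        adj_r2=float(adj_r2),
        F=float(F),
        F_df=(k - 1, dof),
        F_p=F_p,
        aicc=aicc_val,
        n=n,
        k=k,
        K=k + 2,
        rss=sol.rss,
        meta={
            "r2_definition": "1 - RSS_W/TSS_W, TSS_W = intercept-only RSS in the "
                             "whitened metric at lambda_hat",
            "lambda_profile_grid": profile[0].tolist(),
            "lambda_profile_loglik": profile[1].tolist(),
        },
    )


def f_test_term(y: np.ndarray, X: np.ndarray, V: VCV | np.ndarray,
                cols: list[int], lam: float) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F test for a block of columns at a fixed lambda.

    Compares the full design against the design with ``cols`` removed,
    both fitted in the V(lambda)-whitened metric.  Used for multi-level
    factors, where single-coefficient t tests do not test the factor as
    a whole.
    """
    Vm = V.matrix if isinstance(V, VCV) else np.asarray(V, dtype=float)
    W = lambda_transform(Vm, lam)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    keep = [j for j in range(k) if j not in set(cols)]
    full = gls_solve(y, X, W)
    reduced = gls_solve(y, X[:, keep], W)
    q = len(cols)
    dof = n - k
    F = ((reduced.rss - full.rss) / q) / (full.rss / dof)
    return float(F), (q, dof), float(stats.f.sf(F, q, dof))
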