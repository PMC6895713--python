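"""Random-intercept linear mixed model fitted by REML.

Implements the single-grouping-factor model

    y = X beta + Z b + e,   b_i ~ N(0, tau2),   e ~ N(0, sigma2 I)

with a profiled REML criterion over the variance ratio lambda = tau2/sigma2
(closed-form GLS per candidate, exploiting the block structure of
V = sigma2 (I + lambda Z Z')), Satterthwaite degrees of freedom for the
fixed-effect t tests, and Nakagawa–Schielzeth marginal/conditional r2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMResult", "fit_random_intercept"]


@dataclass(frozen=True)
class LMMResult:
    """Fitted random-intercept model."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray  # Satterthwaite approximation per coefficient
    pvalues: np.ndarray
    sigma: float  # residual SD
    tau: float  # random-intercept SD
    cov_beta: np.ndarray
    fitted_fixed: np.ndarray
    blups: dict
    n_obs: int
    n_groups: int
    reml_neg2loglik: float

    def confint(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient t confidence intervals, shape (p, 2)."""
        q = stats.t.ppf(0.5 + level / 2.0, self.df)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])


class _Blocks:
    """Per-group sufficient statistics for V^{-1} products.

    With W = I + lam * Z Z' (block diagonal), the inverse of a block of
    size n_i is I - c_i J with c_i = lam / (1 + lam n_i), so every product
    reduces to group sums.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        _, idx, counts = np.unique(g, return_index=True, return_counts=True)
        self.starts = idx
        self.counts = counts
        self.n, self.p = X.shape
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.Sx = np.add.reduceat(self.X, idx, axis=0)  # per-group column sums
        self.Sy = np.add.reduceat(self.y, idx)

    def gls(self, lam: float):
        c = lam / (1.0 + lam * self.counts)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx  # X' W^-1 X
        bvec = self.Xty - self.Sx.T @ (c * self.Sy)  # X' W^-1 y
        beta = np.linalg.solve(A, bvec)
        r = self.y - self.X @ beta
        Sr = np.add.reduceat(r, self.starts)
        # floor keeps the perfect-fit limit (rss -> 0) finite in the logs
        rss = max(float(r @ r - (c * Sr**2).sum()), 1e-280)
        return A, beta, rss, Sr

    def profiled_neg2reml(self, lam: float) -> float:
        A, _, rss, _ = self.gls(lam)
        logdetW = float(np.log1p(lam * self.counts).sum())
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (self.n - self.p) * np.log(rss) + logdetW + logdetA

    def neg2reml(self, sigma2: float, tau2: float) -> float:
        """Unprofiled REML deviance (beta profiled out) up to a constant."""
        lam = tau2 / sigma2
        A, _, rss, _ = self.gls(lam)
        logdetW = float(np.log1p(lam * self.counts).sum())
        _, logdetA = np.linalg.slogdet(A)
        return (
            self.n * np.log(sigma2)
            + logdetW
            + logdetA
            - self.p * np.log(sigma2)
            + rss / sigma2
            + (self.n - self.p) * np.log(2 * np.pi)
        )

    def cov_beta(self, sigma2: float, tau2: float) -> np.ndarray:
        A, *_ = self.gls(tau2 / sigma2)
        return sigma2 * np.linalg.inv(A)


def _satterthwaite(blocks: _Blocks, sigma2: float, tau2: float) -> np.ndarray:
    """Satterthwaite df per coefficient via the delta method.

    df_j = 2 C_jj^2 / (g' Avar g) with g the gradient of C_jj wrt the
    variance components and Avar their asymptotic covariance from the
    numerical REML Hessian (the lmerTest construction).
    """
    theta = np.array([sigma2, tau2])
    h = np.maximum(1e-7, 1e-4 * np.maximum(theta, sigma2))

    def f(th):
        return 0.5 * blocks.neg2reml(max(th[0], 1e-12), max(th[1], 0.0))

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        avar = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(blocks.p, float(blocks.n - blocks.p))

    grads = np.empty((blocks.p, 2))
    for k in range(2):
        e = np.zeros(2); e[k] = h[k]
        cp = blocks.cov_beta(*(theta + e))
        cm = blocks.cov_beta(*np.maximum(theta - e, [1e-12, 0.0]))
        grads[:, k] = (np.diag(cp) - np.diag(cm)) / (2 * h[k])

    C = blocks.cov_beta(sigma2, tau2)
    df = np.empty(blocks.p)
    for j in range(blocks.p):
        denom = grads[j] @ avar @ grads[j]
        df[j] = 2 * C[j, j] ** 2 / denom if denom > 0 else blocks.n - blocks.p
    # guard against numerically absurd values
    return np.clip(df, 1.0, 10.0 * blocks.n)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> LMMResult:
    """Fit ``y ~ X`` with a random intercept per level of ``groups`` by REML.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design, including the intercept column.
    groups : (n,) group labels (any hashable dtype).
    names : optional coefficient names, defaults to x0..x{p-1}.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size or groups.size != y.size:
        raise ValueError("incompatible shapes for y, X, groups")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed effects ({p})")
    n_groups = np.unique(groups).size
    if n_groups < 2:
        raise ValueError(
            "random intercept is unidentifiable with a single group; need >= 2"
        )
    if names is None:
        names = tuple(f"x{i}" for i in range(p))

    blocks = _Blocks(y, X, groups)
    res = optimize.minimize_scalar(
        lambda lv: blocks.profiled_neg2reml(np.exp(lv)),
        bounds=(-13.8, 13.8),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # compare with the boundary lambda = 0 (no group variance)
    if blocks.profiled_neg2reml(0.0) <= res.fun:
        lam = 0.0
    A, beta, rss, Sr = blocks.gls(lam)
    sigma2 = rss / (n - p)
    tau2 = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    tvalues = beta / se
    if tau2 > 0:
        df = _satterthwaite(blocks, sigma2, tau2)
    else:
        df = np.full(p, float(n - p))
    pvalues = 2.0 * stats.t.sf(np.abs(tvalues), df)

    # BLUPs: b_i = tau2 * sum(resid_i) / (sigma2 + n_i tau2)
    labels = np.unique(groups)
    shrink = tau2 * Sr / (sigma2 + blocks.counts * tau2)
    blups = dict(zip(labels.tolist(), shrink.tolist()))

    return LMMResult(
        names=tuple(names),
        beta=beta,
        se=se,
        tvalues=tvalues,
        df=df,
        pvalues=pvalues,
        sigma=float(np.sqrt(sigma2)),
        tau=float(np.sqrt(tau2)),
        cov_beta=cov_beta,
        fitted_fixed=X @ beta,
        blups=blups,
        n_obs=n,
        n_groups=int(n_groups),
        reml_neg2loglik=blocks.neg2reml(sigma2, max(tau2, 0.0)),
    )
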