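"""Random-effects logistic regression by maximum marginal likelihood.

Fits ``logit P(y=1) = X @ beta + b0_s (+ b1_s * x_slope)`` with independent
Gaussian random effects per grouping unit (subject).  The marginal likelihood
integrates the random effects out per subject:

* one random intercept — adaptive Gauss–Hermite quadrature centred and scaled
  at the per-subject posterior mode (``nagq`` nodes; ``nagq=1`` is the Laplace
  approximation);
* intercept + slope — the Laplace approximation (mode plus curvature), the
  standard default for multi-dimensional random effects.

Wald standard errors come from the numerical Hessian of the marginal
log-likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, roots_hermitenorm
from scipy.stats import norm

__all__ = ["MixedLogitResult", "fit_mixed_logit"]


@dataclass
class MixedLogitResult:
    names: list
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray          # (p, 2): Wald 95% intervals
    cov: np.ndarray               # covariance of the fixed effects
    re_sd: np.ndarray             # random-effect SDs (intercept[, slope])
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def contrast(self, c) -> tuple[float, float]:
        """Estimate and SE of a linear combination ``c @ beta`` (delta method)."""
        c = np.asarray(c, dtype=float)
        return float(c @ self.beta), float(np.sqrt(c @ self.cov @ c))


def _loglik_terms(y, lin):
    # log p(y | lin) = y*lin - log(1 + exp(lin)), stable
    return y * lin - np.logaddexp(0.0, lin)


class _Marginal:
    """Marginal log-likelihood with per-subject mode finding (warm-started)."""

    def __init__(self, y, X, groups, slope, nagq):
        self.y = y
        self.X = X
        self.g = groups
        self.slope = slope
        self.q = 1 if slope is None else 2
        self.S = int(groups.max()) + 1
        self.b = np.zeros((self.S, self.q))
        if self.q == 1:
            self.nodes, self.weights = roots_hermitenorm(nagq)
        self.nagq = nagq

    def _modes(self, eta, d):
        """Newton iteration for the per-subject posterior modes, vectorized.

        Starts from zero every call so the objective is a deterministic
        function of the parameters (warm starts leak state across line-search
        evaluations).
        """
        y, g, S = self.y, self.g, self.S
        b = self.b
        b[:] = 0.0
        for _ in range(60):
            lin = eta + b[g, 0]
            if self.q == 2:
                lin = lin + b[g, 1] * self.slope
            mu = expit(lin)
            r = y - mu
            w = mu * (1.0 - mu) + 1e-12
            g0 = np.bincount(g, weights=r, minlength=S) - b[:, 0] / d[0]
            h00 = np.bincount(g, weights=w, minlength=S) + 1.0 / d[0]
            if self.q == 1:
                step = g0 / h00
                b[:, 0] += np.clip(step, -10, 10)
                if np.max(np.abs(step)) < 1e-9:
                    break
            else:
                x1 = self.slope
                g1 = np.bincount(g, weights=r * x1, minlength=S) - b[:, 1] / d[1]
                h01 = np.bincount(g, weights=w * x1, minlength=S)
                h11 = np.bincount(g, weights=w * x1 * x1, minlength=S) + 1.0 / d[1]
                det = h00 * h11 - h01 * h01
                s0 = (h11 * g0 - h01 * g1) / det
                s1 = (h00 * g1 - h01 * g0) / det
                b[:, 0] += np.clip(s0, -10, 10)
                b[:, 1] += np.clip(s1, -10, 10)
                if max(np.max(np.abs(s0)), np.max(np.abs(s1))) < 1e-9:
                    break
        return b

    def __call__(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        d = np.exp(2.0 * theta[p:])  # random-effect variances
        eta = self.X @ beta
        y, g, S = self.y, self.g, self.S
        b = self._modes(eta, d)

        lin = eta + b[g, 0]
        if self.q == 2:
            lin = lin + b[g, 1] * self.slope
        mu = expit(lin)
        w = mu * (1.0 - mu) + 1e-12
        L = np.bincount(g, weights=_loglik_terms(y, lin), minlength=S)

        if self.q == 1:
            h = np.bincount(g, weights=w, minlength=S) + 1.0 / d[0]
            pen = L - b[:, 0] ** 2 / (2.0 * d[0])
            if self.nagq == 1:
                ll = pen - 0.5 * np.log(d[0] * h)
            else:
                s = 1.0 / np.sqrt(h)                       # (S,)
                zk, wk = self.nodes, self.weights
                M = np.empty((S, zk.size))
                for k, (z, _) in enumerate(zip(zk, wk)):
                    bk = b[:, 0] + s * z
                    link = eta + bk[g]
                    Lk = np.bincount(g, weights=_loglik_terms(y, link), minlength=S)
                    M[:, k] = (Lk - bk**2 / (2.0 * d[0])) - pen + 0.5 * z * z
                Mmax = M.max(axis=1)
                inner = np.log(np.exp(M - Mmax[:, None]) @ wk) + Mmax
                ll = pen + np.log(s) + inner - 0.5 * np.log(2.0 * np.pi * d[0])
            return float(np.sum(ll))

        x1 = self.slope
        h00 = np.bincount(g, weights=w, minlength=S) + 1.0 / d[0]
        h01 = np.bincount(g, weights=w * x1, minlength=S)
        h11 = np.bincount(g, weights=w * x1 * x1, minlength=S) + 1.0 / d[1]
        det = h00 * h11 - h01 * h01
        ll = (
            L
            - b[:, 0] ** 2 / (2.0 * d[0])
            - b[:, 1] ** 2 / (2.0 * d[1])
            - 0.5 * np.log(d[0] * d[1] * det)
        )
        return float(np.sum(ll))


class _Profiled:
    """Laplace likelihood for intercept+slope random effects, with the fixed
    effects profiled out by penalized IRLS (the lme4 strategy: the outer
    optimizer sees only the two variance parameters; ``beta`` sits at the
    joint conditional mode; Wald covariance of ``beta`` is conditional on the
    variance estimates, via the Schur complement of the joint information)."""

    def __init__(self, y, X, groups, slope):
        self.y, self.X, self.g, self.x1 = y, X, groups, slope
        self.S = int(groups.max()) + 1
        self.beta = _start_beta(y, X)
        self.b = np.zeros((self.S, 2))

    def _pirls(self, d, max_iter=50, tol=1e-9):
        """Joint Newton on (beta, b): the sparse (p + 2S) system is solved
        exactly each iteration through the Schur complement over the
        block-diagonal random-effects Hessian.  Stores the fixed-effects
        information (Schur complement) for the conditional Wald covariance."""
        y, X, g, x1, S = self.y, self.X, self.g, self.x1, self.S
        p = X.shape[1]
        beta, b = self.beta, self.b
        info = None
        for _ in range(max_iter):
            lin = X @ beta + b[g, 0] + b[g, 1] * x1
            mu = expit(lin)
            r = y - mu
            w = mu * (1.0 - mu) + 1e-12
            g_beta = X.T @ r
            g0 = np.bincount(g, weights=r, minlength=S) - b[:, 0] / d[0]
            g1 = np.bincount(g, weights=r * x1, minlength=S) - b[:, 1] / d[1]
            h00 = np.bincount(g, weights=w, minlength=S) + 1.0 / d[0]
            h01 = np.bincount(g, weights=w * x1, minlength=S)
            h11 = np.bincount(g, weights=w * x1 * x1, minlength=S) + 1.0 / d[1]
            det = h00 * h11 - h01 * h01
            i00, i01, i11 = h11 / det, -h01 / det, h00 / det
            wx = w[:, None] * X
            A = wx.T @ X
            B0 = np.stack([np.bincount(g, weights=wx[:, j], minlength=S) for j in range(p)], 1)
            B1 = np.stack(
                [np.bincount(g, weights=wx[:, j] * x1, minlength=S) for j in range(p)], 1
            )
            hg0 = i00 * g0 + i01 * g1                      # H^{-1} g_b, per subject
            hg1 = i01 * g0 + i11 * g1
            corr = (
                (B0 * i00[:, None]).T @ B0
                + (B0 * i01[:, None]).T @ B1
                + (B1 * i01[:, None]).T @ B0
                + (B1 * i11[:, None]).T @ B1
            )
            info = A - corr
            rhs = g_beta - (B0.T @ hg0 + B1.T @ hg1)
            try:
                dbeta = np.linalg.solve(info, rhs)
            except np.linalg.LinAlgError:
                dbeta = np.linalg.lstsq(info, rhs, rcond=None)[0]
            dbeta = np.clip(dbeta, -10, 10)
            res0 = g0 - B0 @ dbeta
            res1 = g1 - B1 @ dbeta
            db0 = np.clip(i00 * res0 + i01 * res1, -10, 10)
            db1 = np.clip(i01 * res0 + i11 * res1, -10, 10)
            beta += dbeta
            b[:, 0] += db0
            b[:, 1] += db1
            if max(np.max(np.abs(dbeta)), np.max(np.abs(db0)), np.max(np.abs(db1))) < tol:
                break
        self._info = info
        return beta, b

    def laplace(self, log_sd):
        d = np.exp(2.0 * np.asarray(log_sd))
        beta, b = self._pirls(d)
        y, X, g, x1, S = self.y, self.X, self.g, self.x1, self.S
        lin = X @ beta + b[g, 0] + b[g, 1] * x1
        mu = expit(lin)
        w = mu * (1.0 - mu) + 1e-12
        L = np.bincount(g, weights=_loglik_terms(y, lin), minlength=S)
        h00 = np.bincount(g, weights=w, minlength=S) + 1.0 / d[0]
        h01 = np.bincount(g, weights=w * x1, minlength=S)
        h11 = np.bincount(g, weights=w * x1 * x1, minlength=S) + 1.0 / d[1]
        det = h00 * h11 - h01 * h01
        ll = (
            L
            - b[:, 0] ** 2 / (2.0 * d[0])
            - b[:, 1] ** 2 / (2.0 * d[1])
            - 0.5 * np.log(d[0] * d[1] * det)
        )
        return float(np.sum(ll))

    def beta_cov(self, log_sd):
        """Conditional covariance of beta: inverse Schur complement of the
        joint (beta, b) observed information at the estimates."""
        self._pirls(np.exp(2.0 * np.asarray(log_sd)))
        try:
            return np.linalg.inv(self._info)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(self._info)


def _start_beta(y, X):
    """Pooled (no random effect) logistic fit for starting values."""
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu) + 1e-9
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def fit_mixed_logit(
    y,
    X,
    groups,
    names=None,
    slope=None,
    nagq: int = 9,
    start_sd=(0.8, 0.5),
    maxiter: int = 300,
    compute_cov: bool = True,
) -> MixedLogitResult:
    """Fit the random-effects logistic model.

    Parameters
    ----------
    y, X, groups
        Binary response, fixed-effects design matrix, and integer group codes
        (0..S-1) for the random effects.
    slope
        Optional per-row covariate carrying a second, independent random
        effect (random slope); ``None`` fits a random intercept only.
    nagq
        Quadrature nodes for the intercept-only model (1 = Laplace).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    _, gidx = np.unique(groups, return_inverse=True)
    if slope is not None:
        slope = np.asarray(slope, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single level; cannot fit")
    p = X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]

    if slope is not None:
        prof = _Profiled(y, X, gidx, slope)
        res = optimize.minimize(
            lambda ls: -prof.laplace(ls), np.log(np.asarray(start_sd[:2])),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("mixed-logit fit diverged (non-finite marginal likelihood)")
        log_sd = res.x
        cov = prof.beta_cov(log_sd) if compute_cov else np.full((p, p), np.nan)
        beta = prof.beta.copy()
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        re_sd = np.exp(log_sd)
        loglik = float(-res.fun)
        converged = bool(res.success)
        method = "laplace_profiled"
        diag = {"n_iter": int(res.nit), "message": str(res.message)}
    else:
        marg = _Marginal(y, X, gidx, slope, nagq)
        theta0 = np.concatenate([_start_beta(y, X), np.log(np.asarray(start_sd[:1]))])
        negll = lambda th: -marg(th)
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("mixed-logit fit diverged (non-finite marginal likelihood)")
        theta = res.x
        if compute_cov:
            H = _hessian(negll, theta)
            try:
                cov_all = np.linalg.inv(0.5 * (H + H.T))
            except np.linalg.LinAlgError:
                cov_all = np.linalg.pinv(0.5 * (H + H.T))
            cov = cov_all[:p, :p]
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        else:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
        beta = theta[:p]
        re_sd = np.exp(theta[p:])
        loglik = float(-res.fun)
        converged = bool(res.success)
        method = "agq%d" % nagq
        diag = {"n_iter": int(res.nit), "message": str(res.message)}
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
    return MixedLogitResult(
        names=list(names), beta=beta, se=se, z=z, pvalues=pvals, conf_int=ci,
        cov=cov, re_sd=re_sd, loglik=loglik,
        converged=converged, n_obs=len(y), n_groups=int(gidx.max()) + 1,
        method=method, diagnostics=diag,
    )


def _hessian(f, x, step=1e-4):
    d = len(x)
    H = np.empty((d, d))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H
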