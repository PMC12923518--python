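"""MAP fitting, Laplace model evidence, outlier winsorization, and
random-effects Bayesian model selection (BMS).

Each subject is fitted per candidate model by maximizing log-likelihood +
log-prior on the unconstrained parameter scale (quasi-Newton from several
jittered starts).  The log model evidence is the Laplace approximation at
the MAP; evidences feed the variational random-effects BMS scheme whose
exceedance probabilities are estimated by Monte Carlo draws from the final
Dirichlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import digamma

from .models import ModelSpec, get_model
from .observation import INVALID_CANDIDATE, log_likelihood

__all__ = [
    "FittedModel",
    "BMSResult",
    "fit_map",
    "log_evidence",
    "winsorize_extreme",
    "bms",
    "fit_cohort",
]

_LN2PI = math.log(2.0 * math.pi)


@dataclass
class FittedModel:
    """MAP estimate for one subject under one candidate model."""

    model: str
    x: np.ndarray                 # MAP on the unconstrained scale
    params: dict                  # native scale, including fixed parameters
    loglik: float
    logpost: float                # loglik + logprior at the MAP
    hessian: np.ndarray           # of the NEGATIVE log posterior at the MAP
    converged: bool
    n_restarts: int
    log_evidence: float = np.nan
    evidence_method: str = "laplace"
    diagnostics: dict = field(default_factory=dict)

    @property
    def param_names(self):
        return get_model(self.model).param_names


def _objective(x, spec: ModelSpec, dataset, prior_mean, prior_var):
    params = spec.to_native(x)
    ll = log_likelihood(spec.name, params, dataset)
    if ll <= INVALID_CANDIDATE:
        return 1e10
    lp = -0.5 * np.sum((x - prior_mean) ** 2 / prior_var)
    lp -= 0.5 * np.sum(np.log(2.0 * np.pi * prior_var))
    return -(ll + lp)


def _numeric_hessian(f, x, step=1e-3):
    d = len(x)
    H = np.empty((d, d))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_map(dataset, model: str, priors: dict | None = None, n_restarts: int = 10, seed=0) -> FittedModel:
    """MAP fit of one candidate model to one subject's choices.

    ``priors`` optionally overrides the registry defaults as a mapping
    ``name -> (mean, var)`` on the unconstrained scale.  Starts are the prior
    mean plus Gaussian jitter of one prior SD (the first start is the prior
    mean itself).  Raises ``RuntimeError`` if no restart converges.
    """
    if dataset.schedule.n_trials < 2:
        raise ValueError("dataset must contain at least 2 trials")
    spec = get_model(model)
    prior_mean = spec.prior_means().copy()
    prior_var = spec.prior_vars().copy()
    if priors:
        for i, pd_ in enumerate(spec.params):
            if pd_.name in priors:
                m, v = priors[pd_.name]
                if v <= 0:
                    raise ValueError(f"prior variance for {pd_.name} must be > 0")
                prior_mean[i], prior_var[i] = m, v
    rng = np.random.default_rng(seed)
    prior_sd = np.sqrt(prior_var)

    best = None
    n_ok = 0
    for r in range(n_restarts):
        x0 = prior_mean if r == 0 else prior_mean + prior_sd * rng.standard_normal(len(prior_mean))
        res = optimize.minimize(
            _objective, x0, args=(spec, dataset, prior_mean, prior_var),
            method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"fit_map: no converged restart for model {model!r} "
            f"(subject {getattr(dataset, 'subject_id', '?')})"
        )

    x = best.x
    H = _numeric_hessian(lambda z: _objective(z, spec, dataset, prior_mean, prior_var), x)
    params = spec.to_native(x)
    ll = log_likelihood(model, params, dataset)
    fit = FittedModel(
        model=model, x=x, params=params, loglik=ll, logpost=-best.fun, hessian=H,
        converged=bool(best.success or best.fun < 1e9), n_restarts=n_restarts,
        diagnostics={"n_converged_restarts": n_ok, "objective": float(best.fun)},
    )
    fit.log_evidence = log_evidence(fit, n_trials=dataset.schedule.n_trials)
    return fit


def log_evidence(fit: FittedModel, n_trials: int = 200) -> float:
    """Laplace approximation to the log model evidence.

    ``logpost(MAP) + (d/2) log 2*pi - 0.5 log det H`` with ``H`` the Hessian
    of the negative log posterior.  A Hessian that is not positive definite
    is regularized by flooring its eigenvalues; if it is badly conditioned
    even then, a BIC-style value is returned and flagged in diagnostics.
    """
    d = len(fit.x)
    H = 0.5 * (fit.hessian + fit.hessian.T)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.any(eigvals <= 0):
            floor = max(1e-6, np.abs(eigvals).max() * 1e-8)
            eigvals = np.maximum(eigvals, floor)
            fit.diagnostics["hessian_regularized"] = True
        logdet = float(np.sum(np.log(eigvals)))
        if not math.isfinite(logdet):
            raise np.linalg.LinAlgError
        fit.evidence_method = "laplace"
        return fit.logpost + 0.5 * d * _LN2PI - 0.5 * logdet
    except np.linalg.LinAlgError:
        fit.evidence_method = "bic"
        fit.diagnostics["evidence_fallback"] = "bic"
        return fit.loglik - 0.5 * d * math.log(n_trials)


def winsorize_extreme(values):
    """Flag extreme outliers (beyond Q3 + 3*IQR, linear-interpolation quartiles)
    and replace each by the maximum non-extreme value plus one sample SD of
    the non-extreme values.

    Returns ``(adjusted, report)`` where the report lists index, original and
    replacement for every flagged value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("winsorize_extreme requires at least 4 values")
    if np.ptp(v) == 0:
        return v.copy(), []
    q1, q3 = np.percentile(v, [25, 75])
    fence = q3 + 3.0 * (q3 - q1)
    extreme = v > fence
    if not extreme.any():
        return v.copy(), []
    non = v[~extreme]
    replacement = non.max() + non.std(ddof=1)
    out = v.copy()
    out[extreme] = replacement
    report = [
        {"index": int(i), "original": float(v[i]), "replacement": float(replacement)}
        for i in np.flatnonzero(extreme)
    ]
    return out, report


@dataclass
class BMSResult:
    """Random-effects BMS output over a subjects-by-models evidence matrix."""

    models: list
    alpha: np.ndarray                 # Dirichlet concentrations
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    subject_posteriors: np.ndarray    # subjects x models
    n_samples: int
    seed: int

    @property
    def best_model(self) -> str:
        return self.models[int(np.argmax(self.expected_frequencies))]

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance": self.exceedance.tolist(),
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def bms(
    log_evidences,
    models=None,
    prior_concentration: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects Bayesian model selection (variational Dirichlet scheme).

    Iterates per-subject posterior model probabilities
    ``u_nk  proportional to  exp(lme_nk + digamma(alpha_k) - digamma(sum alpha))``
    against ``alpha = alpha0 + sum_n u_n`` to convergence, then estimates each
    model's exceedance probability — the probability it is the most frequent
    model in the population — from Dirichlet Monte Carlo draws.
    """
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("log_evidences must be a subjects x models matrix with >= 2 models")
    if not np.isfinite(lme).all():
        raise ValueError("log_evidences contains non-finite values")
    n_subj, n_mod = lme.shape
    if models is None:
        models = [f"m{k}" for k in range(n_mod)]

    alpha0 = np.full(n_mod, float(prior_concentration))
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = lme + (digamma(alpha) - digamma(alpha.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    exceedance = np.bincount(np.argmax(draws, axis=1), minlength=n_mod) / float(n_samples)
    return BMSResult(
        models=list(models),
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=exceedance,
        subject_posteriors=u,
        n_samples=int(n_samples),
        seed=int(seed),
    )


def fit_cohort(datasets, models, priors=None, n_restarts: int = 5, seed: int = 0):
    """Fit every candidate model to every subject; returns a tidy fits table.

    Columns: subject_id, model, one column per unconstrained parameter,
    log_evidence, loglik, converged.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    rows, fits = [], {}
    for ds, child in zip(datasets, ss.spawn(len(datasets))):
        sub_seeds = child.spawn(len(models))
        for model, s in zip(models, sub_seeds):
            fit = fit_map(ds, model, priors=priors, n_restarts=n_restarts,
                          seed=np.random.default_rng(s))
            fits[(ds.subject_id, model)] = fit
            row = {"subject_id": ds.subject_id, "model": model}
            for name, xi in zip(fit.param_names, fit.x):
                row[name] = float(xi)
            row["log_evidence"] = float(fit.log_evidence)
            row["loglik"] = float(fit.loglik)
            row["converged"] = bool(fit.converged)
            rows.append(row)
    return pd.DataFrame(rows), fits
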