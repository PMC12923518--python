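"""Choice-behavior statistics: stay/shift tables, mixed-effects logistic
regressions, simple slopes, parameter regressions, and the simulation-based
power harness.

Coding conventions (re-mappable, recorded here and in every result object):
``prev_outcome`` 1 = incurred loss (reference: avoided), ``context`` 1 =
volatile (reference: stable), ``randomization`` 1 = volatile first.  The
loss-magnitude difference (chosen minus unchosen, current trial) and age are
mean-centered once over the analyzed rows / cohort before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import patsy
from scipy.stats import norm

from .mixedlogit import MixedLogitResult, fit_mixed_logit
from .task import draw_asix_years, transform_asix

__all__ = [
    "RegressionResult",
    "score_asix",
    "build_stay_table",
    "fit_mixed_logistic",
    "simple_slopes",
    "fit_parameter_regression",
    "PowerConfig",
    "power_simulation",
    "FORMULAS",
]

FORMULAS = {
    "eq1": "stay ~ prev_outcome * context + lmd_c + age_c + randomization",
    "eq2": "stay ~ prev_outcome * context * asix_z + lmd_c + age_c + randomization",
}


@dataclass
class RegressionResult:
    """Tidy regression output: per-term estimates with Wald inference."""

    terms: list
    estimate: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray
    cov: np.ndarray
    formula: str
    kind: str                      # 'mixed_logistic' or 'ols'
    n_obs: int
    n_subjects: int
    loglik: float = np.nan
    random_sd: np.ndarray | None = None
    converged: bool = True

    def __getitem__(self, term: str) -> float:
        return float(self.estimate[self.terms.index(term)])

    def contrast(self, c) -> tuple[float, float]:
        c = np.asarray(c, dtype=float)
        return float(c @ self.estimate), float(np.sqrt(c @ self.cov @ c))

    def odds_ratio(self, c) -> dict:
        """Odds ratio for a linear contrast of coefficients, with a Wald CI."""
        est, se = self.contrast(c)
        return {
            "or": float(np.exp(est)),
            "ci": [float(np.exp(est - 1.96 * se)), float(np.exp(est + 1.96 * se))],
            "log_odds": est,
            "se": se,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimate,
                "se": self.se,
                "statistic": self.statistic,
                "p": self.pvalues,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
            }
        )

    def to_dict(self) -> dict:
        out = self.to_frame().to_dict(orient="records")
        return {
            "formula": self.formula,
            "kind": self.kind,
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "converged": bool(self.converged),
            "random_sd": None if self.random_sd is None else list(map(float, self.random_sd)),
            "terms": out,
        }


def score_asix(use_records: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Sum per-substance years of regular use and transform across the cohort.

    ``use_records`` has one row per subject and one column per substance
    (years of regular use, >= 0).  Returns ``(total_years, asix_z)`` where the
    transform is square-root then z-score (in that order).
    """
    vals = use_records.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("years of regular use cannot be negative")
    total = pd.Series(vals.sum(axis=1), index=use_records.index, name="asix_years")
    z = pd.Series(transform_asix(total.to_numpy()), index=use_records.index, name="asix_z")
    return total, z


def build_stay_table(datasets, covariates: pd.DataFrame) -> pd.DataFrame:
    """One row per analyzable trial: stay/shift with lagged outcome and context.

    The first trial of the session and the first trial of each context block
    are excluded (no previous outcome within the same contingency regime), so
    a complete 200-trial session contributes 198 rows.  ``covariates`` is
    indexed by or contains ``subject_id`` with ``age``, ``randomization`` and
    either ``asix_z`` or ``asix_years``.
    """
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    if "asix_z" not in cov.columns:
        cov = cov.assign(asix_z=transform_asix(cov["asix_years"].to_numpy()))

    frames = []
    for ds in datasets:
        sched = ds.schedule
        n = sched.n_trials
        t = np.arange(1, n)
        block_start = sched.context[t] != sched.context[t - 1]
        t = t[~block_start]
        chosen = np.where(ds.choice == 1, sched.mag_card1, sched.mag_card2)
        unchosen = np.where(ds.choice == 1, sched.mag_card2, sched.mag_card1)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ds.subject_id,
                    "trial": t + 1,
                    "stay": (ds.choice[t] == ds.choice[t - 1]).astype(int),
                    "prev_outcome": ds.outcome[t - 1].astype(int),
                    "context": (sched.context[t] == "volatile").astype(int),
                    "lmd": chosen[t] - unchosen[t],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["lmd_c"] = table["lmd"] - table["lmd"].mean()

    age = cov["age"].astype(float)
    age_c = age - age.mean()
    table = table.join(age_c.rename("age_c"), on="subject_id")
    rand = cov["randomization"]
    rand_code = (rand == "volatile_first").astype(int) if rand.dtype == object else rand.astype(int)
    table = table.join(rand_code.rename("randomization"), on="subject_id")
    table = table.join(cov["asix_z"], on="subject_id")
    return table.drop(columns=["lmd"])


def fit_mixed_logistic(
    table: pd.DataFrame, formula_spec: str = "eq1", nagq: int = 9
) -> RegressionResult:
    """Random-intercept-per-subject logistic regression of stay choices.

    ``formula_spec`` is ``'eq1'`` (task effects), ``'eq2'`` (ASI-X
    moderation), or any patsy formula over the stay-table columns.  Estimation
    maximizes the adaptive-quadrature marginal likelihood; Wald z tests.
    """
    formula = FORMULAS.get(formula_spec, formula_spec)
    if table["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects for a mixed model")
    if table["stay"].nunique() < 2:
        raise ValueError("stay has a single level; cannot fit")
    ymat, X = patsy.dmatrices(formula, table, return_type="dataframe")
    res = fit_mixed_logit(
        ymat.to_numpy().ravel(),
        X.to_numpy(),
        table["subject_id"].to_numpy(),
        names=list(X.columns),
        nagq=nagq,
    )
    if not res.converged:
        raise RuntimeError(f"mixed model did not converge: {res.diagnostics.get('message')}")
    return RegressionResult(
        terms=res.names, estimate=res.beta, se=res.se, statistic=res.z,
        pvalues=res.pvalues, conf_int=res.conf_int, cov=res.cov, formula=formula,
        kind="mixed_logistic", n_obs=res.n_obs, n_subjects=res.n_groups,
        loglik=res.loglik, random_sd=res.re_sd, converged=res.converged,
    )


def _interaction_term(terms, a, b):
    for name in (f"{a}:{b}", f"{b}:{a}"):
        if name in terms:
            return name
    raise KeyError(f"no interaction between {a!r} and {b!r} among terms {terms}")


def simple_slopes(result: RegressionResult, focal: str, moderator: str, levels) -> pd.DataFrame:
    """Conditional slope of ``focal`` at fixed ``moderator`` levels.

    The slope at level ``l`` is ``b_focal + l * b_interaction``; its SE comes
    from the coefficient covariance by the delta method.
    """
    if focal not in result.terms:
        raise KeyError(f"term {focal!r} not in model")
    inter = _interaction_term(result.terms, focal, moderator)
    rows = []
    for lev in levels:
        c = np.zeros(len(result.terms))
        c[result.terms.index(focal)] = 1.0
        c[result.terms.index(inter)] = float(lev)
        est, se = result.contrast(c)
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "level": lev,
                "slope": est,
                "se": se,
                "z": z,
                "p": 2.0 * norm.sf(abs(z)),
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
            }
        )
    return pd.DataFrame(rows)


def fit_parameter_regression(cohort: pd.DataFrame, parameter: str) -> RegressionResult:
    """OLS of a fitted model parameter on ASI-X, randomization and age.

    ``cohort`` joins subject covariates with fitted parameters (winsorization
    of the inverse-temperature estimates is applied upstream).
    """
    import statsmodels.formula.api as smf

    df = cohort.copy()
    if "age_c" not in df.columns:
        df["age_c"] = df["age"].astype(float) - df["age"].astype(float).mean()
    if df["randomization"].dtype == object:
        df["randomization"] = (df["randomization"] == "volatile_first").astype(int)
    formula = f"{parameter} ~ asix_z + randomization + age_c"
    model = smf.ols(formula, data=df)
    fitted = model.fit()
    # rank check: statsmodels silently drops nothing, so flag collinearity
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        corr = np.corrcoef(model.exog[:, 1:], rowvar=False)
        raise ValueError(f"design matrix is rank deficient (rank {rank}); predictor correlations:\n{corr}")
    ci = fitted.conf_int().to_numpy()
    return RegressionResult(
        terms=list(fitted.params.index), estimate=fitted.params.to_numpy(),
        se=fitted.bse.to_numpy(), statistic=fitted.tvalues.to_numpy(),
        pvalues=fitted.pvalues.to_numpy(), conf_int=ci,
        cov=fitted.cov_params().to_numpy(), formula=formula, kind="ols",
        n_obs=int(fitted.nobs), n_subjects=int(fitted.nobs),
        loglik=float(fitted.llf),
    )


@dataclass
class PowerConfig:
    """Generative settings for the power simulation (logged with every run).

    Fixed effects sit at magnitudes like the study's stay/shift estimates; the
    subject level carries a random intercept and a random previous-outcome
    slope — individual differences in outcome sensitivity are the phenomenon
    the moderation test is about, and without slope heterogeneity the
    interaction test at 198 trials/subject is essentially never underpowered.
    """

    intercept: float = 0.4
    prev_outcome: float = -0.669
    context: float = -0.101
    asix: float = -0.1
    prev_context: float = 0.124
    context_asix: float = 0.083
    three_way: float = 0.0
    lmd: float = -0.05
    age: float = 0.0
    randomization: float = 0.0
    re_intercept_sd: float = 0.8
    re_slope_sd: float = 0.5
    p_prev_incurred: float = 0.4
    trials_per_subject: int = 198
    asix_zero_fraction: float = 0.25
    asix_gamma_shape: float = 1.5
    asix_gamma_scale: float = 8.0


# column order of the simulated design matrix
_POWER_TERMS = [
    "intercept", "prev_outcome", "context", "asix_z", "prev:context",
    "prev:asix", "context:asix", "prev:context:asix", "lmd_c", "age_c",
    "randomization",
]


def _simulate_power_cohort(n_subjects, effect_size, cfg: PowerConfig, rng):
    T = cfg.trials_per_subject
    n = n_subjects * T
    g = np.repeat(np.arange(n_subjects), T)

    years = draw_asix_years(
        n_subjects, cfg.asix_zero_fraction, cfg.asix_gamma_shape, cfg.asix_gamma_scale, rng
    )
    asix = transform_asix(years)[g]
    age = rng.normal(0.0, 12.0, n_subjects)[g]
    rand = (rng.random(n_subjects) < 0.5).astype(float)[g]
    prev = (rng.random(n) < cfg.p_prev_incurred).astype(float)
    context = np.tile(np.repeat([0.0, 1.0], T // 2 + T % 2)[:T], n_subjects)
    lmd = rng.uniform(1, 5, n) - rng.uniform(1, 5, n)
    lmd -= lmd.mean()

    X = np.column_stack([
        np.ones(n), prev, context, asix, prev * context, prev * asix,
        context * asix, prev * context * asix, lmd, age, rand,
    ])
    beta = np.array([
        cfg.intercept, cfg.prev_outcome, cfg.context, cfg.asix, cfg.prev_context,
        effect_size, cfg.context_asix, cfg.three_way, cfg.lmd, cfg.age,
        cfg.randomization,
    ])
    b0 = rng.normal(0.0, cfg.re_intercept_sd, n_subjects)[g]
    b1 = rng.normal(0.0, cfg.re_slope_sd, n_subjects)[g]
    eta = X @ beta + b0 + b1 * prev
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, X, g, prev


def power_simulation(
    effect_size: float,
    n_subjects: int = 137,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    config: PowerConfig | None = None,
) -> dict:
    """Simulated power for the previous-outcome x ASI-X interaction.

    Each replicate simulates a cohort from the stay/shift moderation model
    (fixed effects plus random intercept and random previous-outcome slope),
    re-fits the same model, and applies the Wald test to the interaction at
    ``alpha``.  Returns the rejection fraction with a Wilson binomial CI;
    failed fits are excluded and counted.
    """
    if n_replicates < 50:
        raise ValueError("use at least 50 replicates")
    cfg = config or PowerConfig()
    rng = np.random.default_rng(seed)
    j = _POWER_TERMS.index("prev:asix")
    rejected = n_failed = 0
    for _ in range(n_replicates):
        y, X, g, prev = _simulate_power_cohort(n_subjects, effect_size, cfg, rng)
        try:
            res = fit_mixed_logit(
                y, X, g, names=_POWER_TERMS, slope=prev,
                start_sd=(cfg.re_intercept_sd, max(cfg.re_slope_sd, 0.1)),
            )
            pval = res.pvalues[j]
            if not np.isfinite(pval):
                raise RuntimeError("non-finite p-value")
        except (RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if pval < alpha:
            rejected += 1
    n_eff = n_replicates - n_failed
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(rejected, n_eff, alpha=0.05, method="wilson")
    return {
        "power": rejected / n_eff,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_replicates": n_replicates,
        "n_failed": n_failed,
        "alpha": alpha,
        "effect_size": effect_size,
        "n_subjects": n_subjects,
        "config": asdict(cfg),
    }
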