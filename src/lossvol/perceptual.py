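"""Trial-by-trial belief updating for the candidate learning models.

All models track the predicted probability that the reference card (card 1,
"black") is the losing card on the upcoming trial.  The binary outcome ``u``
is 1 when card 1 turned out to be the losing card.  Candidates:

* ``rw``    — Rescorla–Wagner delta rule with fixed learning rate ``alpha``.
* ``k1``    — Sutton's K1 scheme: a delta rule whose learning rate adapts on a
  log scale, driven by the recent correlation of prediction errors.
* ``hgf2``  — two-level binary Hierarchical Gaussian Filter; the tendency
  ``mu2`` (log-odds of loss) receives precision-weighted updates whose speed is
  governed by the log-volatility ``omega``.
* ``hgf3``  — three-level binary HGF; a third level tracks log-volatility
  itself, with coupling ``kappa`` and meta-volatility ``theta``.

``*_loss`` variants differ only in the observation model (free loss
sensitivity ``rho``), so they share these recursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import ParameterError

__all__ = [
    "BeliefTrajectory",
    "TrajectoryError",
    "rw_update",
    "k1_update",
    "hgf2_update",
    "hgf3_update",
    "run_trajectory",
    "INITIAL_STATE",
]

# Fixed (not fitted) initial states: neutral prior belief s_hat = 0.5.
INITIAL_STATE = {"v": 0.5, "mu2": 0.0, "sigma2": 1.0, "mu3": 1.0, "sigma3": 1.0, "h": 0.0}


def _exp(x: float) -> float:
    """exp with a capped argument so extreme optimizer candidates stay finite."""
    return math.exp(min(x, 700.0))


class TrajectoryError(RuntimeError):
    """Belief update produced an invalid state (e.g. non-positive precision)."""

    def __init__(self, message: str, trial: int | None = None):
        if trial is not None:
            message = f"trial {trial}: {message}"
        super().__init__(message)
        self.trial = trial


@dataclass
class BeliefTrajectory:
    """Per-trial perceptual states for one subject.

    ``s_hat[t]`` is the prediction *before* outcome ``t`` is observed; the
    state arrays hold the posterior after the trial-``t`` update.
    """

    model: str
    s_hat: np.ndarray
    delta1: np.ndarray
    mu2: np.ndarray | None = None
    sigma2: np.ndarray | None = None
    eps2: np.ndarray | None = None
    mu3: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    learning_rate: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.s_hat)

    def to_frame(self):
        import pandas as pd

        cols = {"trial": np.arange(1, len(self) + 1), "s_hat": self.s_hat, "delta1": self.delta1}
        for name in ("mu2", "sigma2", "eps2", "mu3", "sigma3", "learning_rate"):
            arr = getattr(self, name)
            if arr is not None:
                cols[name] = arr
        return pd.DataFrame(cols)


def rw_update(v: float, u: int, alpha: float) -> float:
    """Rescorla–Wagner delta rule: v' = v + alpha * (u - v).

    The update is total on the closed interval alpha in [0, 1] (0 = no
    learning, 1 = one-step memory); fitting works on the open interval via
    the logit transform.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"parameter alpha={alpha!r} must lie in [0, 1]")
    return v + alpha * (u - v)


def k1_update(
    v: float, b: float, h: float, u: int, k1_mu: float
) -> tuple[float, float, float, float]:
    """One step of Sutton's K1 adaptive-gain delta rule.

    The log learning rate ``b`` moves with the correlation of the current
    prediction error and a decaying trace ``h`` of past errors; the rate is
    capped at 1 so the probability estimate stays in [0, 1].

    Returns ``(v', b', h', rate)``.
    """
    if k1_mu < 0:
        raise ParameterError(f"parameter k1_mu={k1_mu!r} must be >= 0")
    delta = u - v
    b_new = b + k1_mu * delta * h
    rate = 1.0 if b_new >= 0 else math.exp(b_new)
    v_new = v + rate * delta
    h_new = h * max(0.0, 1.0 - rate) + rate * delta
    if not (math.isfinite(v_new) and math.isfinite(b_new) and math.isfinite(h_new)):
        raise TrajectoryError("K1 state diverged to non-finite values")
    return v_new, b_new, h_new, rate


def hgf2_update(
    mu2: float, sigma2: float, u: int, omega: float
) -> tuple[float, float, float, float, float]:
    """One step of the two-level binary HGF.

    s_hat     = logistic(mu2)
    sigma2hat = sigma2 + exp(omega)          (prior variance of the tendency)
    pi2       = 1/sigma2hat + s_hat(1-s_hat) (posterior precision)
    mu2'      = mu2 + (1/pi2)(u - s_hat)
    sigma2'   = 1/pi2

    Returns ``(mu2', sigma2', s_hat, delta1, eps2)`` where ``delta1 = u - s_hat``
    and ``eps2 = (1/pi2) * delta1`` is the precision-weighted prediction error.
    """
    if sigma2 <= 0:
        raise TrajectoryError(f"sigma2={sigma2!r} must be positive")
    s_hat = 1.0 / (1.0 + math.exp(-mu2)) if mu2 >= 0 else math.exp(mu2) / (1.0 + math.exp(mu2))
    sigma2hat = sigma2 + _exp(omega)
    pi2 = 1.0 / sigma2hat + s_hat * (1.0 - s_hat)
    delta1 = u - s_hat
    eps2 = delta1 / pi2
    return mu2 + eps2, 1.0 / pi2, s_hat, delta1, eps2


def hgf3_update(
    mu2: float,
    sigma2: float,
    mu3: float,
    sigma3: float,
    u: int,
    omega: float,
    kappa: float,
    theta: float,
) -> tuple[float, float, float, float, float, float, float]:
    """One step of the three-level binary HGF.

    Level 2 is the two-level update with effective log-volatility
    ``kappa*mu3 + omega``; level 3 receives the volatility prediction error
    ``delta2`` through the weight ``w2 = v/(sigma2 + v)`` with step variance
    ``theta``.  Parameter regimes that drive the level-3 precision
    non-positive raise :class:`TrajectoryError` (the fit candidate is
    rejected).

    Returns ``(mu2', sigma2', mu3', sigma3', s_hat, delta1, eps2)``.
    """
    if sigma2 <= 0 or sigma3 <= 0:
        raise TrajectoryError("sigma2 and sigma3 must be positive")
    if kappa <= 0 or theta < 0:
        raise ParameterError(f"parameter kappa={kappa!r} must be > 0 and theta={theta!r} >= 0")
    s_hat = 1.0 / (1.0 + math.exp(-mu2)) if mu2 >= 0 else math.exp(mu2) / (1.0 + math.exp(mu2))
    v = _exp(kappa * mu3 + omega)
    sigma2hat = sigma2 + v
    pi2 = 1.0 / sigma2hat + s_hat * (1.0 - s_hat)
    delta1 = u - s_hat
    eps2 = delta1 / pi2
    mu2_new = mu2 + eps2
    sigma2_new = 1.0 / pi2

    w2 = v / sigma2hat
    delta2 = (sigma2_new + eps2 * eps2) / sigma2hat - 1.0
    pi3hat = 1.0 / (sigma3 + theta)
    pi3 = pi3hat + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0 or not math.isfinite(pi3):
        raise TrajectoryError(f"level-3 precision non-positive (pi3={pi3!r})")
    mu3_new = mu3 + 0.5 * kappa * w2 * delta2 / pi3
    sigma3_new = 1.0 / pi3
    return mu2_new, sigma2_new, mu3_new, sigma3_new, s_hat, delta1, eps2


def run_trajectory(model: str, params: dict, outcomes: np.ndarray) -> BeliefTrajectory:
    """Fold the model's update rule over a binary outcome sequence.

    ``outcomes[t] = 1`` means card 1 was the losing card on trial ``t``.
    Update errors are re-raised with the trial index attached.
    """
    u = np.asarray(outcomes)
    if u.size and not np.isin(u, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    n = u.size
    family = "hgf3" if model.startswith("hgf3") else (
        "hgf2" if model.startswith("hgf2") else model
    )

    s_hat = np.empty(n)
    delta1 = np.empty(n)
    if family == "rw":
        alpha = params["alpha"]
        if not 0.0 <= alpha <= 1.0:
            raise ParameterError(f"parameter alpha={alpha!r} must lie in [0, 1]")
        v = INITIAL_STATE["v"]
        lr = np.empty(n)
        for t in range(n):
            s_hat[t] = v
            delta1[t] = u[t] - v
            v = v + alpha * delta1[t]
            lr[t] = alpha
        return BeliefTrajectory(model, s_hat, delta1, learning_rate=lr)

    if family == "k1":
        v, b, h = INITIAL_STATE["v"], params["k1_b0"], INITIAL_STATE["h"]
        k1_mu = params["k1_mu"]
        lr = np.empty(n)
        for t in range(n):
            s_hat[t] = v
            try:
                v, b, h, rate = k1_update(v, b, h, int(u[t]), k1_mu)
            except TrajectoryError as exc:
                raise TrajectoryError(str(exc), trial=t + 1) from exc
            delta1[t] = u[t] - s_hat[t]
            lr[t] = rate
        return BeliefTrajectory(model, s_hat, delta1, learning_rate=lr)

    if family == "hgf2":
        omega = params["omega"]
        mu2, sigma2 = INITIAL_STATE["mu2"], INITIAL_STATE["sigma2"]
        mu2_arr, sig2_arr, eps2_arr = np.empty(n), np.empty(n), np.empty(n)
        for t in range(n):
            try:
                mu2, sigma2, sh, d1, e2 = hgf2_update(mu2, sigma2, int(u[t]), omega)
            except TrajectoryError as exc:
                raise TrajectoryError(str(exc), trial=t + 1) from exc
            s_hat[t], delta1[t] = sh, d1
            mu2_arr[t], sig2_arr[t], eps2_arr[t] = mu2, sigma2, e2
        return BeliefTrajectory(model, s_hat, delta1, mu2=mu2_arr, sigma2=sig2_arr, eps2=eps2_arr)

    if family == "hgf3":
        omega, kappa, theta = params["omega"], params["kappa"], params["theta"]
        mu2, sigma2 = INITIAL_STATE["mu2"], INITIAL_STATE["sigma2"]
        mu3, sigma3 = INITIAL_STATE["mu3"], INITIAL_STATE["sigma3"]
        mu2_arr, sig2_arr, eps2_arr = np.empty(n), np.empty(n), np.empty(n)
        mu3_arr, sig3_arr = np.empty(n), np.empty(n)
        for t in range(n):
            try:
                mu2, sigma2, mu3, sigma3, sh, d1, e2 = hgf3_update(
                    mu2, sigma2, mu3, sigma3, int(u[t]), omega, kappa, theta
                )
            except TrajectoryError as exc:
                raise TrajectoryError(str(exc), trial=t + 1) from exc
            s_hat[t], delta1[t] = sh, d1
            mu2_arr[t], sig2_arr[t], eps2_arr[t] = mu2, sigma2, e2
            mu3_arr[t], sig3_arr[t] = mu3, sigma3
        return BeliefTrajectory(
            model, s_hat, delta1, mu2=mu2_arr, sigma2=sig2_arr, eps2=eps2_arr,
            mu3=mu3_arr, sigma3=sig3_arr,
        )

    raise KeyError(f"unknown model {model!r}")
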