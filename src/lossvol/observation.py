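"""Loss-frame softmax observation model.

Beliefs and loss magnitudes are mapped to expected (negative) values
``v = -p_loss * magnitude**rho`` and a choice is drawn from
``P(card 1) = logistic(beta * (v1 - v2))``.  The loss-sensitivity parameter
``rho`` enters as a power on magnitude — a multiplicative scale would be
exactly collinear with the inverse temperature ``beta`` in a loss-only
two-option softmax, whereas the power form leaves both identifiable while
keeping the reading that larger ``rho`` means greater magnitude sensitivity.
"""

from __future__ import annotations

import math

import numpy as np

from .models import ParameterError, get_model
from .perceptual import TrajectoryError, run_trajectory

__all__ = [
    "expected_loss_value",
    "choice_probability",
    "trial_choice_probabilities",
    "log_likelihood",
    "INVALID_CANDIDATE",
]

# Sentinel log-likelihood for parameter vectors whose trajectory diverges;
# the optimizer treats such candidates as arbitrarily bad but finite-safe.
INVALID_CANDIDATE = -1e12

_PCLIP = 1e-12


def expected_loss_value(p_loss, magnitude, rho):
    """Expected value of choosing a card: ``-p_loss * magnitude**rho`` (<= 0)."""
    magnitude = np.asarray(magnitude, dtype=float)
    if np.any(magnitude <= 0):
        raise ValueError("magnitude must be positive")
    if np.any(np.asarray(rho) <= 0):
        raise ParameterError(f"parameter rho={rho!r} must be > 0")
    # power computed in log space with a capped exponent so extreme rho
    # candidates explored by the optimizer stay finite
    powm = np.exp(np.minimum(rho * np.log(magnitude), 500.0))
    return -np.asarray(p_loss, dtype=float) * powm


def choice_probability(v1, v2, beta):
    """Softmax probability of choosing card 1: ``logistic(beta*(v1 - v2))``."""
    if np.any(np.asarray(beta) < 0):
        raise ParameterError(f"parameter beta={beta!r} must be >= 0")
    from scipy.special import expit

    return expit(beta * (np.asarray(v1, float) - np.asarray(v2, float)))


def trial_choice_probabilities(model: str, params: dict, schedule, outcomes=None):
    """Per-trial probability of choosing card 1 given a schedule.

    ``outcomes`` is the card-1 loss indicator sequence the learner observes;
    by default it is taken from the schedule (full feedback: the correct card
    is revealed every trial regardless of choice).
    """
    spec = get_model(model)
    spec.validate(params)
    u = schedule.u_card1 if outcomes is None else np.asarray(outcomes)
    traj = run_trajectory(model, params, u)
    s_hat = np.clip(traj.s_hat, _PCLIP, 1.0 - _PCLIP)
    rho = params.get("rho", 1.0)
    v1 = expected_loss_value(s_hat, schedule.mag_card1, rho)
    v2 = expected_loss_value(1.0 - s_hat, schedule.mag_card2, rho)
    return choice_probability(v1, v2, params["beta"]), traj


def log_likelihood(model: str, params: dict, dataset) -> float:
    """Total choice log-likelihood of one subject under one candidate model.

    The perceptual trajectory is run over the full session in presentation
    order with a single parameter set; probabilities are clamped away from
    0/1 so the value is always finite.  A diverging trajectory returns the
    :data:`INVALID_CANDIDATE` sentinel instead of raising.
    """
    try:
        p1, _ = trial_choice_probabilities(model, params, dataset.schedule)
    except TrajectoryError:
        return INVALID_CANDIDATE
    p1 = np.clip(p1, _PCLIP, 1.0 - _PCLIP)
    chose1 = dataset.choice == 1
    ll = float(np.sum(np.log(np.where(chose1, p1, 1.0 - p1))))
    return ll if math.isfinite(ll) else INVALID_CANDIDATE
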