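"""Loss-frame probabilistic learning task: schedules, agents, synthetic cohorts.

The session has 200 trials in two contiguous 100-trial contexts.  In the
stable context one card loses with probability 0.75 and the other 0.25 for
all 100 trials; in the volatile context the assignment is 0.80/0.20 and
reverses every 25 trials.  Both cards carry loss magnitudes drawn
independently and uniformly on [$1, $5] each trial (continuous draws,
rounded to whole dollars for display only).  Choosing the incorrect card
loses that card's magnitude; choosing the correct card loses $0.

The cohort generator stands in for the study sample: subject-level
generative parameters are linked linearly, on their unconstrained scales, to
a z-scored square-root-transformed years-of-regular-substance-use covariate
(ASI-X) with a point mass at zero, plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import get_model
from .observation import trial_choice_probabilities

__all__ = [
    "N_TRIALS",
    "TrialSchedule",
    "SubjectDataset",
    "CohortConfig",
    "generate_schedule",
    "draw_magnitudes",
    "simulate_agent",
    "draw_asix_years",
    "transform_asix",
    "generate_cohort",
]

N_TRIALS = 200
BLOCK = 100
REVERSAL = 25
STABLE_P = 0.75
VOLATILE_P = 0.80


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class TrialSchedule:
    """Per-trial contingencies, magnitudes and context labels for one session."""

    context: np.ndarray        # 'stable' / 'volatile' per trial
    p_loss_card1: np.ndarray   # probability card 1 is the losing card
    mag_card1: np.ndarray      # dollars, in [1, 5]
    mag_card2: np.ndarray
    correct_card: np.ndarray   # 1 or 2; the card that does NOT lose
    block_order: str           # 'stable_first' or 'volatile_first'

    @property
    def n_trials(self) -> int:
        return len(self.correct_card)

    @property
    def u_card1(self) -> np.ndarray:
        """Binary outcome sequence for the learner: 1 = card 1 lost."""
        return (self.correct_card == 2).astype(int)


@dataclass
class SubjectDataset:
    """One subject's schedule plus choices and outcomes; the unit of fitting."""

    subject_id: str
    schedule: TrialSchedule
    choice: np.ndarray       # 1 or 2
    outcome: np.ndarray      # 1 = incurred loss (chose the losing card)
    loss_amount: np.ndarray  # 0 if avoided, chosen card's magnitude if incurred

    def __post_init__(self):
        incurred = self.choice != self.schedule.correct_card
        if not np.array_equal(self.outcome.astype(bool), incurred):
            raise ValueError("outcome must be 1 exactly when choice != correct_card")
        if not np.array_equal(self.loss_amount == 0, self.outcome == 0):
            raise ValueError("loss_amount must be 0 exactly when the loss was avoided")


def generate_schedule(block_order: str, seed) -> TrialSchedule:
    """Draw one task schedule.

    Which card starts as the high-loss card is randomized per subject in both
    contexts; the volatile assignment reverses at trial offsets 25, 50, 75
    within its block.  ``correct_card`` is drawn Bernoulli per trial from the
    card-1 loss probability.
    """
    if block_order not in ("stable_first", "volatile_first"):
        raise ValueError(f"invalid block_order {block_order!r}")
    rng = _rng(seed)

    stable_high = rng.random() < 0.5     # card 1 is the 0.75-loss card?
    stable_p = np.full(BLOCK, STABLE_P if stable_high else round(1 - STABLE_P, 2))

    vol_high = rng.random() < 0.5
    vol_lo = round(1 - VOLATILE_P, 2)
    vol_p = np.empty(BLOCK)
    for i in range(BLOCK // REVERSAL):
        p = VOLATILE_P if (vol_high ^ (i % 2 == 1)) else vol_lo
        vol_p[i * REVERSAL:(i + 1) * REVERSAL] = p

    if block_order == "stable_first":
        p_loss = np.concatenate([stable_p, vol_p])
        context = np.array(["stable"] * BLOCK + ["volatile"] * BLOCK)
    else:
        p_loss = np.concatenate([vol_p, stable_p])
        context = np.array(["volatile"] * BLOCK + ["stable"] * BLOCK)

    mag1, mag2 = draw_magnitudes(N_TRIALS, rng)
    card1_loses = rng.random(N_TRIALS) < p_loss
    correct = np.where(card1_loses, 2, 1)
    return TrialSchedule(context, p_loss, mag1, mag2, correct, block_order)


def draw_magnitudes(n_trials: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Two independent continuous-uniform loss magnitudes on [1, 5] per trial."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    return rng.uniform(1.0, 5.0, n_trials), rng.uniform(1.0, 5.0, n_trials)


def simulate_agent(model: str, params: dict, schedule: TrialSchedule, seed) -> SubjectDataset:
    """Simulate one agent choosing under a candidate model on a fixed schedule.

    Choices are sampled from the observation model's per-trial choice
    probabilities computed from the perceptual trajectory; the learner
    observes the revealed correct card on every trial (full feedback).
    """
    spec = get_model(model)
    spec.validate(params)
    rng = _rng(seed)
    p1, _ = trial_choice_probabilities(model, params, schedule)
    choice = np.where(rng.random(schedule.n_trials) < p1, 1, 2)
    outcome = (choice != schedule.correct_card).astype(int)
    chosen_mag = np.where(choice == 1, schedule.mag_card1, schedule.mag_card2)
    loss_amount = np.where(outcome == 1, chosen_mag, 0.0)
    return SubjectDataset("sim", schedule, choice, outcome, loss_amount)


def draw_asix_years(n: int, zero_fraction: float, shape: float, scale: float, seed) -> np.ndarray:
    """Lifetime years of regular substance use: a point mass at zero plus a gamma tail."""
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must lie in [0, 1]")
    rng = _rng(seed)
    years = rng.gamma(shape, scale, n)
    years[rng.random(n) < zero_fraction] = 0.0
    return years


def transform_asix(total_years) -> np.ndarray:
    """Square-root transform then z-score (sample SD) across the cohort."""
    years = np.asarray(total_years, dtype=float)
    if np.any(years < 0):
        raise ValueError("years of regular use cannot be negative")
    root = np.sqrt(years)
    sd = root.std(ddof=1)
    if sd == 0:
        import warnings

        warnings.warn("ASI-X has zero variance across the cohort; returning zeros")
        return np.zeros_like(root)
    return (root - root.mean()) / sd


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    ``parameter_links`` maps each fitted parameter (unconstrained scale) to
    its linear coefficient on the z-scored transformed ASI-X covariate;
    ``parameter_means``/``parameter_sds`` give the population intercept and
    residual SD on the same scale.  Defaults follow the study's cohort size,
    its zero-use fraction, and regression-scale link magnitudes.
    """

    n_subjects: int = 137
    model: str = "hgf2_loss"
    asix_zero_fraction: float = 0.25
    asix_gamma_shape: float = 1.5
    asix_gamma_scale: float = 8.0
    parameter_links: dict = field(
        default_factory=lambda: {"omega": 0.18, "beta": -0.307, "rho": 0.14}
    )
    parameter_means: dict = field(
        default_factory=lambda: {"omega": -3.0, "beta": 0.5, "rho": 0.5}
    )
    parameter_sds: dict = field(
        default_factory=lambda: {"omega": 1.0, "beta": 0.5, "rho": 0.5}
    )
    age_mean: float = 40.0
    age_sd: float = 12.0
    age_range: tuple = (18.0, 65.0)
    seed: int = 0


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectDataset], pd.DataFrame]:
    """Build a full synthetic cohort with covariate-linked generative parameters.

    Returns the per-subject datasets and a covariate table that records the
    true unconstrained-scale parameters (columns ``true_<name>``) for
    recovery tests.
    """
    spec = get_model(config.model)
    rng = _rng(config.seed)
    n = config.n_subjects

    years = draw_asix_years(
        n, config.asix_zero_fraction, config.asix_gamma_shape, config.asix_gamma_scale, rng
    )
    asix_z = transform_asix(years)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    randomization = np.where(rng.random(n) < 0.5, "stable_first", "volatile_first")

    datasets, rows = [], []
    for i in range(n):
        sub = f"S{i + 1:03d}"
        true_unc = {}
        params = dict(spec.fixed)
        for pd_ in spec.params:
            link = config.parameter_links.get(pd_.name, 0.0)
            mean = config.parameter_means.get(pd_.name, pd_.prior_mean)
            sd = config.parameter_sds.get(pd_.name, 0.5)
            x = mean + link * asix_z[i] + rng.normal(0.0, sd)
            true_unc[pd_.name] = x
            params[pd_.name] = pd_.to_native(x)
        schedule = generate_schedule(randomization[i], rng)
        ds = simulate_agent(config.model, params, schedule, rng)
        ds.subject_id = sub
        datasets.append(ds)
        row = {
            "subject_id": sub,
            "asix_years": years[i],
            "asix_z": asix_z[i],
            "age": age[i],
            "randomization": randomization[i],
        }
        row.update({f"true_{k}": v for k, v in true_unc.items()})
        rows.append(row)
    return datasets, pd.DataFrame(rows)
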