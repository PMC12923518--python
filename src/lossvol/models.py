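"""Model registry: candidate learning models, parameter transforms, default priors.

Each candidate couples a perceptual (belief-update) model with the loss-frame
softmax observation model.  Parameters are fitted on an unconstrained scale
(identity for the HGF volatility ``omega``, log for strictly positive
parameters, logit for rates in (0, 1)); priors are Gaussian on that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ParamDef", "ModelSpec", "MODELS", "get_model", "ParameterError"]


class ParameterError(ValueError):
    """A parameter violates its native-scale constraint."""


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p = e / (1.0 + e)
    return min(max(p, 1e-12), 1.0 - 1e-12)


# transform: native -> unconstrained; inverse: unconstrained -> native
_TRANSFORMS: dict[str, tuple[Callable[[float], float], Callable[[float], float]]] = {
    "identity": (lambda x: x, lambda y: y),
    # inverse exp with clamped argument so extreme optimizer candidates map
    # to finite, strictly positive native values
    "log": (math.log, lambda y: math.exp(min(max(y, -700.0), 700.0))),
    "logit": (_logit, _expit),
}


@dataclass(frozen=True)
class ParamDef:
    """One fitted parameter: its transform and Gaussian prior (unconstrained scale)."""

    name: str
    transform: str
    prior_mean: float
    prior_var: float

    def to_unconstrained(self, native: float) -> float:
        fwd, _ = _TRANSFORMS[self.transform]
        try:
            return fwd(native)
        except ValueError as exc:
            raise ParameterError(
                f"{self.name}={native!r} outside the domain of the {self.transform} transform"
            ) from exc

    def to_native(self, unconstrained: float) -> float:
        _, inv = _TRANSFORMS[self.transform]
        return inv(unconstrained)


@dataclass(frozen=True)
class ModelSpec:
    """A fittable candidate: perceptual + observation parameters and fixed values."""

    name: str
    perceptual: tuple[ParamDef, ...]
    observation: tuple[ParamDef, ...]
    fixed: dict[str, float]

    @property
    def params(self) -> tuple[ParamDef, ...]:
        return self.perceptual + self.observation

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def to_native(self, x: np.ndarray) -> dict[str, float]:
        """Map an unconstrained vector to a full native-scale parameter dict."""
        out = dict(self.fixed)
        for pd, xi in zip(self.params, x):
            out[pd.name] = pd.to_native(float(xi))
        return out

    def to_unconstrained(self, params: dict[str, float]) -> np.ndarray:
        return np.array([pd.to_unconstrained(params[pd.name]) for pd in self.params])

    def prior_means(self) -> np.ndarray:
        return np.array([p.prior_mean for p in self.params])

    def prior_vars(self) -> np.ndarray:
        return np.array([p.prior_var for p in self.params])

    def validate(self, params: dict[str, float]) -> None:
        """Check native-scale constraints, naming the offending parameter."""
        checks = {
            "alpha": lambda v: 0.0 < v < 1.0,
            "beta": lambda v: v >= 0.0,
            "rho": lambda v: v > 0.0,
            "kappa": lambda v: v > 0.0,
            "theta": lambda v: v > 0.0,
            "k1_mu": lambda v: v >= 0.0,
        }
        for name in self.param_names:
            if name in params and name in checks and not checks[name](params[name]):
                raise ParameterError(f"parameter {name}={params[name]!r} violates its constraint")


_BETA = ParamDef("beta", "log", 0.0, 4.0)
_RHO = ParamDef("rho", "log", 0.0, 1.0)
_OMEGA = ParamDef("omega", "identity", -3.0, 16.0)
_ALPHA = ParamDef("alpha", "logit", 0.0, 4.0)
_K1_MU = ParamDef("k1_mu", "log", -3.0, 16.0)
_K1_B0 = ParamDef("k1_b0", "identity", -2.0, 4.0)
_THETA = ParamDef("theta", "log", -6.0, 16.0)

MODELS: dict[str, ModelSpec] = {
    "rw": ModelSpec("rw", (_ALPHA,), (_BETA,), {"rho": 1.0}),
    "k1": ModelSpec("k1", (_K1_MU, _K1_B0), (_BETA,), {"rho": 1.0}),
    "hgf2": ModelSpec("hgf2", (_OMEGA,), (_BETA,), {"rho": 1.0}),
    "hgf2_loss": ModelSpec("hgf2_loss", (_OMEGA,), (_BETA, _RHO), {}),
    "hgf3": ModelSpec("hgf3", (_OMEGA, _THETA), (_BETA,), {"rho": 1.0, "kappa": 1.0}),
    "hgf3_loss": ModelSpec("hgf3_loss", (_OMEGA, _THETA), (_BETA, _RHO), {"kappa": 1.0}),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
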