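"""Generative choice models for the two-alternative localization tasks.

Three model families produce the probability of the *primary* response (West
port in the arena tasks, Left port in the platform tasks):

``world_sinusoid`` / ``head_sinusoid``
    A sinusoidal activation of the primary response,

        z = beta0 + beta1 * cos(theta - beta2)

    with theta the speaker angle in the respective frame; the alternative
    response has activation 1 - z.  A softmax with inverse temperature
    beta_inv_temp converts the activation pair into choice probabilities.

``head_offset``
    A head-centered responder that aims at the port ``beta_offset`` degrees
    away from the head-centered sound angle.  The aimed-at location, mapped
    into the arena frame, is platform independent: wrap(theta_world -
    beta_offset).  When the target is not an active port, one of three
    compensation strategies converts it into activations for the two active
    ports: ``guess`` (split evenly), ``nearest`` (all activation on the
    closer port, split if equidistant) or ``weighted`` (activation of each
    port proportional to the distance from the target to the *other* port).
    The same softmax then yields choice probabilities.

Activations are treated as unconstrained real scores: the parameter bounds
used in fitting allow z slightly outside [0, 1], and the softmax is well
defined for any real activations, so no clipping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .geometry import (
    PortLayout,
    TaskCondition,
    circular_difference,
    is_on_slot,
    wrap_angle,
)

__all__ = [
    "PARAM_BOUNDS",
    "ModelParams",
    "ModelSpec",
    "ChoiceDistribution",
    "sinusoidal_activation",
    "softmax_choice",
    "offset_target",
    "compensate",
    "response_probability",
    "primary_probability",
    "SIMULATION_PRESETS",
    "get_preset",
]

FAMILIES = ("world_sinusoid", "head_sinusoid", "head_offset")
STRATEGIES = ("none", "guess", "nearest", "weighted")

#: Box constraints used for fitting (lower, upper) per parameter.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "beta0": (0.0, 1.0),
    "beta1": (0.0, 0.5),
    "beta2": (-180.0, 180.0),
    "beta_inv_temp": (1e-4, 20.0),
    "beta_offset": (-180.0, 180.0),
}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a choice model.

    beta0
        response bias: baseline activation of the primary response.
    beta1
        modulation depth: sensitivity of the activation to speaker angle.
    beta2
        peak response angle (degrees): speaker angle at which the primary
        response is most likely.
    beta_inv_temp
        softmax inverse temperature; 0 gives random choice, large values
        give near-deterministic choice.
    beta_offset
        response offset angle (degrees), head-offset family only.
    """

    beta0: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    beta_inv_temp: float = 1.0
    beta_offset: float | None = None

    def validate(self, family: str) -> None:
        names = param_names(family)
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{family} requires parameter {name}")
            lo, hi = PARAM_BOUNDS[name]
            if not (lo - 1e-9 <= value <= hi + 1e-9):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")


def param_names(family: str) -> tuple[str, ...]:
    """Free parameters of a family (the offset family has only two)."""
    if family in ("world_sinusoid", "head_sinusoid"):
        return ("beta0", "beta1", "beta2", "beta_inv_temp")
    if family == "head_offset":
        return ("beta_offset", "beta_inv_temp")
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus strategy, response space and parameters."""

    family: str
    params: ModelParams
    strategy: str = "none"
    response_space: str = "EastWest"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if (self.strategy == "none") != (self.family != "head_offset"):
            # A strategy is meaningful only for the offset family; the offset
            # family with strategy "none" is allowed but errors on null-port
            # targets when evaluated.
            if self.family != "head_offset":
                raise ValueError("strategy applies to the head_offset family only")
        if self.family == "head_offset" and self.response_space != "EastWest":
            raise ValueError("head_offset models respond at arena (EastWest) ports")

    def with_params(self, params: ModelParams) -> "ModelSpec":
        return replace(self, params=params)


@dataclass(frozen=True)
class ChoiceDistribution:
    """Probability of the primary response (West or Left) and its complement."""

    p_primary: float

    def __post_init__(self):
        if not (-1e-12 <= self.p_primary <= 1 + 1e-12):
            raise ValueError(f"p_primary={self.p_primary} outside [0, 1]")
        object.__setattr__(self, "p_primary", float(np.clip(self.p_primary, 0.0, 1.0)))

    @property
    def p_secondary(self) -> float:
        return 1.0 - self.p_primary


def sinusoidal_activation(theta, params: ModelParams):
    """Activation z = beta0 + beta1 * cos(theta - beta2), theta in degrees."""
    theta = np.asarray(theta, dtype=float)
    z = params.beta0 + params.beta1 * np.cos(np.deg2rad(theta - params.beta2))
    return float(z) if z.ndim == 0 else z


def softmax_choice(z_primary, z_secondary, beta_inv_temp: float):
    """Two-option softmax: p = exp(e*z1) / (exp(e*z1) + exp(e*z2)).

    Equivalent to a logistic in beta_inv_temp * (z_primary - z_secondary);
    beta_inv_temp = 0 yields 0.5 for any activations.
    """
    if beta_inv_temp < 0:
        raise ValueError("inverse temperature must be non-negative")
    diff = np.asarray(z_primary, dtype=float) - np.asarray(z_secondary, dtype=float)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-beta_inv_temp * diff))
    return float(p) if p.ndim == 0 else p


def offset_target(theta_head, beta_offset):
    """Head-frame response location y = wrap(theta_head - beta_offset)."""
    return wrap_angle(np.asarray(theta_head, dtype=float) - beta_offset)


def compensate(target_world, layout: PortLayout, strategy: str, *,
               require_slot: bool = True):
    """Activation pair (a_primary, a_secondary) for a world-frame target.

    If the target lies on an active port all activation goes to that port.
    Otherwise the strategy decides: ``guess`` splits evenly, ``nearest``
    favors the closer active port (even split if equidistant) and
    ``weighted`` assigns each port activation proportional to the target's
    distance from the *other* port, so the nearer port is weighted higher
    and equidistant targets degrade to an even split.

    Scalar or array ``target_world``.  With ``require_slot`` the target must
    lie on the 30-degree grid (the generative, discrete-port reading); model
    fitting evaluates the same formulas at free-valued offsets.
    """
    if strategy not in ("guess", "nearest", "weighted"):
        raise ValueError(f"unknown compensation strategy {strategy!r}")
    scalar = np.ndim(target_world) == 0
    target = np.atleast_1d(np.asarray(target_world, dtype=float))
    if require_slot:
        for t in target:
            if not is_on_slot(t):
                raise ValueError(f"target {t} is not on a 30-degree slot")
    d_primary = np.abs(circular_difference(target, layout.primary))
    d_secondary = np.abs(circular_difference(target, layout.secondary))
    tol = 1e-9
    at_primary = d_primary < tol
    at_secondary = d_secondary < tol

    if strategy == "guess":
        a_primary = np.full(target.shape, 0.5)
    elif strategy == "nearest":
        a_primary = np.where(d_primary < d_secondary - tol, 1.0,
                             np.where(d_secondary < d_primary - tol, 0.0, 0.5))
    else:  # weighted
        a_primary = d_secondary / (d_primary + d_secondary)
    a_primary = np.where(at_primary, 1.0, np.where(at_secondary, 0.0, a_primary))
    a_secondary = 1.0 - a_primary
    if scalar:
        return float(a_primary[0]), float(a_secondary[0])
    return a_primary, a_secondary


def primary_probability(spec: ModelSpec, theta_head, theta_world,
                        layout: PortLayout | None = None, *,
                        require_slot: bool = True):
    """Vectorized probability of the primary response for given conditions."""
    params = spec.params
    params.validate(spec.family)
    theta_head = np.asarray(theta_head, dtype=float)
    theta_world = np.asarray(theta_world, dtype=float)
    if spec.family == "world_sinusoid":
        z = sinusoidal_activation(theta_world, params)
        return softmax_choice(z, 1.0 - np.asarray(z), params.beta_inv_temp)
    if spec.family == "head_sinusoid":
        z = sinusoidal_activation(theta_head, params)
        return softmax_choice(z, 1.0 - np.asarray(z), params.beta_inv_temp)
    # head_offset: aim beta_offset away from the head-centered sound, then
    # express the aimed-at location in the arena frame.
    if layout is None:
        raise ValueError("head_offset models need a port layout")
    target_head = offset_target(theta_head, params.beta_offset)
    platform = circular_difference(theta_world, theta_head)
    target_world = wrap_angle(target_head + platform)
    if spec.strategy == "none":
        d1 = np.abs(circular_difference(target_world, layout.primary))
        d2 = np.abs(circular_difference(target_world, layout.secondary))
        if np.any((d1 > 1e-9) & (d2 > 1e-9)):
            raise ValueError(
                "head_offset without a compensation strategy targets a null "
                "location; choose strategy 'guess', 'nearest' or 'weighted'"
            )
        a1 = np.where(d1 <= 1e-9, 1.0, 0.0)
        a2 = 1.0 - a1
    else:
        a1, a2 = compensate(target_world, layout, spec.strategy, require_slot=require_slot)
    return softmax_choice(a1, a2, params.beta_inv_temp)


def response_probability(spec: ModelSpec, condition: TaskCondition,
                         layout: PortLayout | None = None) -> ChoiceDistribution:
    """Choice distribution of a model for a single task condition."""
    p = primary_probability(spec, condition.speaker_head, condition.speaker_world, layout)
    return ChoiceDistribution(p_primary=float(p))


# --- Printed simulation parameter presets -------------------------------

def _sin_params() -> ModelParams:
    return ModelParams(beta0=0.5, beta1=0.3, beta2=0.0, beta_inv_temp=2.0)


#: Named parameter sets used for the illustrative simulations.  The offset
#: presets aim 90 degrees clockwise of the head-centered sound angle; under
#: this package's sign convention (left of the midline negative) that is
#: beta_offset = +90, which sends sounds from in front to the right-hand
#: side and sounds from behind to the left.
SIMULATION_PRESETS: dict[str, ModelSpec] = {
    "world_sim": ModelSpec(family="world_sinusoid", params=_sin_params()),
    "head_west_sim": ModelSpec(family="head_sinusoid", params=_sin_params()),
    "head_offset_guess_sim": ModelSpec(
        family="head_offset", strategy="guess",
        params=ModelParams(beta_offset=90.0, beta_inv_temp=1.0)),
    "head_offset_nearest_sim": ModelSpec(
        family="head_offset", strategy="nearest",
        params=ModelParams(beta_offset=90.0, beta_inv_temp=1.0)),
    "head_offset_sim": ModelSpec(
        family="head_offset", strategy="weighted",
        params=ModelParams(beta_offset=90.0, beta_inv_temp=1.0)),
    "head_task_sim": ModelSpec(family="head_sinusoid", params=_sin_params(),
                               response_space="LeftRight"),
}


def get_preset(name: str) -> ModelSpec:
    try:
        return SIMULATION_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; one of {sorted(SIMULATION_PRESETS)}") from None


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serializable form of a model spec (inverse of :func:`spec_from_dict`)."""
    d = {"family": spec.family, "strategy": spec.strategy,
         "response_space": spec.response_space}
    d["params"] = {k: getattr(spec.params, k) for k in
                   ("beta0", "beta1", "beta2", "beta_inv_temp", "beta_offset")
                   if getattr(spec.params, k) is not None}
    return d


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(family=d["family"], strategy=d.get("strategy", "none"),
                     response_space=d.get("response_space", "EastWest"),
                     params=ModelParams(**d.get("params", {})))
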