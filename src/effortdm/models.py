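"""Candidate effort-by-reward psychometric functions.

Three families are compared throughout the pipeline: a linear ramp, a
logistic (sigmoid) discount curve, and a stretched-exponential (Weibull)
curve.  Effort is expressed as a fraction of the task variant's maximum
(button presses or minutes), reward on its raw currency scale, so the
sigmoid ``bias`` is the reward level at which effort reaches half its
ceiling and ``sigma`` (the inverse gradient) is the additional reward
needed to accelerate effort expenditure — larger sigma means a shallower,
less reward-sensitive curve.

All evaluators are pure functions of numpy arrays; clipping to the unit
interval is the simulator's job, not theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "ParameterPoint",
    "MODELS",
    "LINEAR",
    "SIGMOID",
    "WEIBULL",
    "eval_linear",
    "eval_sigmoid",
    "eval_weibull",
    "evaluate",
    "simulate_observations",
]


@dataclass(frozen=True)
class ModelSpec:
    """A psychometric model family and its free-parameter layout.

    ``transform`` maps each free parameter to its link ("identity" or
    "log"); fitting happens in the unconstrained space, so a log link
    guarantees positivity in natural space.  ``fixed`` holds parameters
    clamped to a constant (the sigmoid asymptote c = 1, so the family has
    exactly two free parameters: bias and sigma).
    """

    family: str
    parameter_names: tuple[str, ...]
    transform: dict[str, str] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.parameter_names:
            link = self.transform.get(name, "identity")
            if link not in ("identity", "log"):
                raise ValueError(f"unknown link {link!r} for {name!r}")
        overlap = set(self.parameter_names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")

    @property
    def unconstrained_names(self) -> tuple[str, ...]:
        """Free-parameter names in fitting space (log-linked get a log_ prefix)."""
        return tuple(
            f"log_{n}" if self.transform.get(n) == "log" else n
            for n in self.parameter_names
        )

    def to_natural(self, theta: np.ndarray) -> dict[str, float]:
        """Map an unconstrained vector to a natural-space parameter dict."""
        theta = np.asarray(theta, dtype=float)
        out = {}
        for i, name in enumerate(self.parameter_names):
            v = theta[i]
            out[name] = float(np.exp(v)) if self.transform.get(name) == "log" else float(v)
        return out

    def to_unconstrained(self, values: dict[str, float]) -> np.ndarray:
        """Map natural-space values to the unconstrained fitting vector."""
        out = np.empty(len(self.parameter_names))
        for i, name in enumerate(self.parameter_names):
            v = values[name]
            if self.transform.get(name) == "log":
                if v <= 0:
                    raise ValueError(f"{name} must be positive for a log link, got {v}")
                out[i] = np.log(v)
            else:
                out[i] = v
        return out


@dataclass
class ParameterPoint:
    """One realization of a model's parameters, tagged with its space."""

    values: dict[str, float]
    space_tag: str = "natural"

    def __post_init__(self) -> None:
        if self.space_tag not in ("natural", "unconstrained"):
            raise ValueError(f"bad space_tag {self.space_tag!r}")

    def validate(self, spec: ModelSpec) -> None:
        """Check keys match the spec and natural-space domain constraints hold."""
        expected = set(spec.parameter_names) | {"noise_sd"}
        extra = set(self.values) - expected
        if extra:
            raise ValueError(f"unexpected parameters {extra} for family {spec.family}")
        missing = set(spec.parameter_names) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters {missing} for family {spec.family}")
        if self.space_tag != "natural":
            return
        v = self.values
        for positive in ("sigma", "S", "L", "A"):
            if positive in v and v[positive] <= 0:
                raise ValueError(f"{positive} must be > 0, got {v[positive]}")
        if "A" in v and v["A"] > 1.5:
            raise ValueError(f"asymptote A must be in (0, 1.5], got {v['A']}")


LINEAR = ModelSpec(family="linear", parameter_names=("m", "c"))
SIGMOID = ModelSpec(
    family="sigmoid",
    parameter_names=("bias", "sigma"),
    transform={"sigma": "log"},
    fixed={"c": 1.0},
)
WEIBULL = ModelSpec(
    family="weibull",
    parameter_names=("A", "L", "S"),
    transform={"A": "log", "L": "log", "S": "log"},
)

MODELS: dict[str, ModelSpec] = {m.family: m for m in (LINEAR, SIGMOID, WEIBULL)}


def eval_linear(x, m: float, c: float):
    """Linear effort-reward ramp y = m*x + c (unclipped)."""
    return m * np.asarray(x, dtype=float) + c


def eval_sigmoid(x, bias: float, sigma: float, c: float = 1.0):
    """Logistic discount curve y = c / (1 + exp(-(x - bias)/sigma)).

    ``bias`` translates the curve left-right (reward needed to initiate
    effort); ``sigma`` > 0 is the inverse gradient (reward insensitivity).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z = (np.asarray(x, dtype=float) - bias) / sigma
    return c * expit(z)


def eval_weibull(x, A: float, L: float, S: float):
    """Stretched-exponential curve y = A * (1 - 2^(-(x*L)^S)).

    Starts at 0 for zero reward, rises with latency 1/L and abruptness S
    toward the asymptote A.  Requires x >= 0, L > 0, S > 0.
    """
    if L <= 0 or S <= 0:
        raise ValueError(f"L and S must be > 0, got L={L}, S={S}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("weibull curve is defined for non-negative rewards only")
    return A * (1.0 - np.exp2(-((x * L) ** S)))


_EVALUATORS = {
    "linear": eval_linear,
    "sigmoid": eval_sigmoid,
    "weibull": eval_weibull,
}


def evaluate(spec: ModelSpec, params: ParameterPoint | dict[str, float], x):
    """Evaluate a model family at rewards ``x`` with natural-space parameters."""
    if isinstance(params, ParameterPoint):
        if params.space_tag != "natural":
            raise ValueError("evaluate expects natural-space parameters")
        values = params.values
    else:
        values = params
    kwargs = {k: v for k, v in values.items() if k != "noise_sd"}
    kwargs.update(spec.fixed)
    return _EVALUATORS[spec.family](x, **kwargs)


def simulate_observations(
    model: ModelSpec,
    params: ParameterPoint | dict[str, float],
    rewards,
    noise_sd: float,
    rng_seed=None,
) -> np.ndarray:
    """Simulate noisy normalized-effort observations at the given rewards.

    y_i = clip(f(x_i) + eps_i, 0, 1) with eps_i ~ Normal(0, noise_sd^2).
    Deterministic under a fixed seed; ``rng_seed`` may be an int or a
    numpy Generator.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rewards = np.asarray(rewards, dtype=float)
    y = np.asarray(evaluate(model, params, rewards), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator
        ) else rng_seed
        y = y + rng.normal(0.0, noise_sd, size=rewards.shape)
    return np.clip(y, 0.0, 1.0)
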