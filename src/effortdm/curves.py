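"""Build per-subject, per-condition effort-by-reward discount curves.

Raw trials are reduced to one (reward, normalized effort) point per
retained reward level.  External condition: the maximum accepted effort
offer at each reward level (zero when every offer was rejected —
unwilling to initiate).  Internal condition: the mean indicated effort
across repetitions of the level.  Efforts are normalized by the variant's
maximum so curves from the physical (presses) and cognitive (minutes)
variants live on the same [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import TaskDesign

__all__ = [
    "EffortCurve",
    "EmptyCurveError",
    "build_external_curve",
    "build_internal_curve",
    "apply_cognitive_exclusion",
    "curves_from_trials",
]


class EmptyCurveError(ValueError):
    """Raised when no trials (or no retained reward levels) remain."""


@dataclass(frozen=True)
class EffortCurve:
    """One subject x condition discount curve: the unit of model fitting."""

    subject_id: str
    condition: str
    rewards: tuple[float, ...]
    efforts: tuple[float, ...]  # normalized to [0, 1]
    n_raw_trials: int

    def __post_init__(self) -> None:
        if len(self.rewards) != len(self.efforts):
            raise ValueError("rewards and efforts must be the same length")
        if len(self.rewards) == 0:
            raise EmptyCurveError(f"empty curve for {self.subject_id}/{self.condition}")
        r = np.asarray(self.rewards)
        if not np.all(np.diff(r) > 0):
            raise ValueError("rewards must be strictly increasing")
        e = np.asarray(self.efforts)
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("efforts must lie in [0, 1]")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.rewards, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.efforts, dtype=float)


def build_external_curve(trials: pd.DataFrame, design: TaskDesign) -> EffortCurve:
    """Per reward level, the maximum accepted offer normalized by max effort."""
    _check_single(trials, "external")
    efforts = []
    levels = sorted(trials["reward"].unique())
    for level in levels:
        at_level = trials[trials["reward"] == level]
        accepted = at_level[at_level["response"].astype(str).str.upper() == "Y"]
        best = accepted["offered_effort"].astype(float).max() if len(accepted) else 0.0
        efforts.append(float(best) / design.max_effort)
    return EffortCurve(
        subject_id=str(trials["subject_id"].iloc[0]),
        condition="external",
        rewards=tuple(float(v) for v in levels),
        efforts=tuple(efforts),
        n_raw_trials=len(trials),
    )


def build_internal_curve(trials: pd.DataFrame, design: TaskDesign) -> EffortCurve:
    """Per reward level, the mean indicated effort normalized by max effort."""
    _check_single(trials, "internal")
    levels = sorted(trials["reward"].unique())
    efforts = []
    for level in levels:
        at_level = trials[trials["reward"] == level]
        indicated = at_level["response"].astype(float)
        efforts.append(float(indicated.mean()) / design.max_effort)
    return EffortCurve(
        subject_id=str(trials["subject_id"].iloc[0]),
        condition="internal",
        rewards=tuple(float(v) for v in levels),
        efforts=tuple(np.clip(efforts, 0.0, 1.0)),
        n_raw_trials=len(trials),
    )


def apply_cognitive_exclusion(curve: EffortCurve, cap: float = 200.0) -> EffortCurve:
    """Drop reward levels above the cap (internal responses are unbounded there)."""
    keep = [i for i, r in enumerate(curve.rewards) if r <= cap]
    if not keep:
        raise EmptyCurveError(
            f"all reward levels above cap {cap} for {curve.subject_id}/{curve.condition}"
        )
    return EffortCurve(
        subject_id=curve.subject_id,
        condition=curve.condition,
        rewards=tuple(curve.rewards[i] for i in keep),
        efforts=tuple(curve.efforts[i] for i in keep),
        n_raw_trials=curve.n_raw_trials,
    )


def curves_from_trials(
    trials: pd.DataFrame, design: TaskDesign, reward_cap: float | None = None
) -> list[EffortCurve]:
    """Build every subject x condition curve from a long trial table.

    ``reward_cap`` applies the cognitive-variant exclusion of reward
    levels whose internal responses were unbounded; defaults to 200 for
    the cognitive variant and no cap for the physical variant.
    """
    required = {"subject_id", "condition", "reward", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if reward_cap is None and design.variant == "cognitive":
        reward_cap = 200.0
    builders = {"internal": build_internal_curve, "external": build_external_curve}
    curves = []
    for (sid, cond), group in trials.groupby(["subject_id", "condition"], sort=True):
        curve = builders[str(cond)](group, design)
        if reward_cap is not None:
            curve = apply_cognitive_exclusion(curve, reward_cap)
        curves.append(curve)
    return curves


def curves_to_frame(curves: list[EffortCurve]) -> pd.DataFrame:
    """Tidy (subject_id, condition, reward, effort) table for serialization."""
    rows = [
        {"subject_id": c.subject_id, "condition": c.condition, "reward": r, "effort": e}
        for c in curves
        for r, e in zip(c.rewards, c.efforts)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "condition", "reward", "effort"])


def _check_single(trials: pd.DataFrame, condition: str) -> None:
    if len(trials) == 0:
        raise EmptyCurveError("no trials supplied")
    conds = set(trials["condition"].unique())
    if conds != {condition}:
        raise ValueError(f"expected only {condition!r} trials, got {conds}")
    if trials["subject_id"].nunique() != 1:
        raise ValueError("curve builders take one subject at a time")
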