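"""Synthetic cohort generator for the internal-external motivation task (IMT).

The IMT measures willingness to exert effort for money in two interleaved
conditions: *external*, where the subject accepts or rejects an offered
(effort, reward) pair with a Y/N response, and *internal*, where the
subject freely indicates the maximum effort they would expend for each
reward.  Two variants exist — physical (3-70 button presses for
$0.25-$2.00) and cognitive (1-200 minutes of serial-threes counting for
£1-£500, levels above £200 excluded from analysis).

The generator draws each subject's latent effort-reward curve as a
sigmoid with condition-specific bias and (log-)sigma, then simulates
internal bar positions with Gaussian noise and external Y/N choices with
a logistic rule around the latent threshold.  A true-parameter table is
returned alongside the trials so recovery can be scored, plus a
questionnaire table in which anticipatory-pleasure scores load negatively
on internal bias (higher bias against initiating effort goes with more
anticipatory anhedonia, i.e. lower TEPS-anticipatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import eval_sigmoid

__all__ = [
    "TaskDesign",
    "CohortSpec",
    "default_design",
    "default_cohort_spec",
    "draw_subject_parameters",
    "generate_cohort",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["subject_id", "condition", "reward", "offered_effort", "response", "work_flag"]

CONDITIONS = ("internal", "external")


@dataclass(frozen=True)
class TaskDesign:
    """Structural constants of one IMT variant.

    ``reps_per_level`` is the number of internal-condition repetitions of
    each reward level; the external condition crosses every reward level
    with every entry of ``effort_offer_levels``, so both conditions have
    ``len(reward_levels) * len(effort_offer_levels)`` == 64 trials under
    the physical defaults (128 total, matching the task's trial count).
    """

    variant: str
    reward_levels: tuple[float, ...]
    max_effort: float
    effort_offer_levels: tuple[float, ...]
    reps_per_level: int
    work_probability: float

    def __post_init__(self) -> None:
        if self.variant not in ("physical", "cognitive"):
            raise ValueError(f"unknown variant {self.variant!r}")
        rl = np.asarray(self.reward_levels)
        if not np.all(np.diff(rl) > 0):
            raise ValueError("reward_levels must be strictly increasing")
        eo = np.asarray(self.effort_offer_levels)
        if np.any(eo <= 0) or np.any(eo > self.max_effort):
            raise ValueError("effort offers must lie in (0, max_effort]")
        if self.reps_per_level < 1:
            raise ValueError("reps_per_level must be >= 1")
        if not 0 <= self.work_probability <= 1:
            raise ValueError("work_probability must be in [0, 1]")

    @property
    def n_trials_internal(self) -> int:
        return len(self.reward_levels) * self.reps_per_level

    @property
    def n_trials_external(self) -> int:
        return len(self.reward_levels) * len(self.effort_offer_levels)

    @property
    def n_trials(self) -> int:
        return self.n_trials_internal + self.n_trials_external


def default_design(variant: str) -> TaskDesign:
    """Default task structure for the physical or cognitive IMT variant."""
    if variant == "physical":
        return TaskDesign(
            variant="physical",
            reward_levels=tuple(np.arange(1, 9) * 0.25),
            max_effort=70.0,
            effort_offer_levels=tuple(np.linspace(3.0, 70.0, 8)),
            reps_per_level=8,
            work_probability=0.30,
        )
    if variant == "cognitive":
        # 1-2-5 ladder capped at £200: magnitudes above £200 are excluded
        # from analysis because the internal condition is unbounded there.
        return TaskDesign(
            variant="cognitive",
            reward_levels=(1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0),
            max_effort=200.0,
            effort_offer_levels=tuple(np.linspace(1.0, 200.0, 8)),
            reps_per_level=1,
            work_probability=0.30,
        )
    raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Generative assumptions for one synthetic cohort.

    Per-condition group means/SDs describe the Gaussian population the
    latent (bias, log sigma) pairs are drawn from; ``noise_sd`` is the
    internal-condition observation noise in normalized-effort units;
    ``choice_temperature`` (natural effort units) softens the external
    accept/reject rule; ``teps_loading`` is the slope of
    TEPS-anticipatory on internal bias (negative: more bias, more
    anticipatory anhedonia).
    """

    n_subjects: int = 26
    bias_mean: dict[str, float] = field(
        default_factory=lambda: {"internal": 1.15, "external": 0.90}
    )
    bias_sd: dict[str, float] = field(
        default_factory=lambda: {"internal": 0.25, "external": 0.25}
    )
    log_sigma_mean: dict[str, float] = field(
        default_factory=lambda: {"internal": float(np.log(0.35)), "external": float(np.log(0.25))}
    )
    log_sigma_sd: dict[str, float] = field(
        default_factory=lambda: {"internal": 0.30, "external": 0.30}
    )
    noise_sd: float = 0.05
    choice_temperature: float = 5.0
    teps_loading: float = -8.0
    teps_anticipatory_intercept: float = 40.0
    teps_residual_sd: float = 4.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in (self.bias_sd, self.log_sigma_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("group SDs must be >= 0")

    def as_null(self) -> "CohortSpec":
        """Zero-effect variant: both conditions share the external means."""
        return replace(
            self,
            bias_mean={c: self.bias_mean["external"] for c in CONDITIONS},
            log_sigma_mean={c: self.log_sigma_mean["external"] for c in CONDITIONS},
        )

    def to_dict(self) -> dict:
        return asdict(self)


def default_cohort_spec(variant: str = "physical", null: bool = False, rng_seed=None) -> CohortSpec:
    """Default generative spec per variant.

    The physical defaults encode the direction of the reported effects:
    the internal (self-generated) condition has a larger bias away from
    effort and larger reward insensitivity than the external condition.
    Cognitive-variant values are scaled to the £1-£200 reward range and
    minute-scale effort.
    """
    if variant == "physical":
        spec = CohortSpec(rng_seed=rng_seed)
    elif variant == "cognitive":
        spec = CohortSpec(
            n_subjects=28,
            bias_mean={"internal": 40.0, "external": 25.0},
            bias_sd={"internal": 12.0, "external": 10.0},
            log_sigma_mean={
                "internal": float(np.log(20.0)),
                "external": float(np.log(15.0)),
            },
            log_sigma_sd={"internal": 0.30, "external": 0.30},
            noise_sd=0.05,
            choice_temperature=15.0,
            teps_loading=-0.2,
            rng_seed=rng_seed,
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return spec.as_null() if null else spec


def draw_subject_parameters(spec: CohortSpec, rng=None) -> pd.DataFrame:
    """Draw the latent per-subject, per-condition (bias, sigma) table only.

    Fast path used for generator calibration checks that do not need trials.
    """
    rng = _as_rng(rng, spec)
    rows = []
    for sid in range(spec.n_subjects):
        for cond in CONDITIONS:
            bias = rng.normal(spec.bias_mean[cond], spec.bias_sd[cond])
            sigma = float(np.exp(rng.normal(spec.log_sigma_mean[cond], spec.log_sigma_sd[cond])))
            rows.append(
                {
                    "subject_id": f"s{sid:03d}",
                    "condition": cond,
                    "bias": bias,
                    "sigma": sigma,
                    "noise_sd": spec.noise_sd,
                }
            )
    return pd.DataFrame(rows)


def _as_rng(rng, spec: CohortSpec) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = spec.rng_seed
    return np.random.default_rng(rng)


def generate_cohort(
    design: TaskDesign, spec: CohortSpec, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: (trial table, true-parameter table, questionnaires).

    Internal trials: indicated effort = clip(max_effort * sigmoid(reward)
    + Normal(0, noise_sd * max_effort), 0, max_effort).  External trials:
    P(accept offer e at reward x) = logistic((max_effort * sigmoid(x) - e)
    / choice_temperature).  ``work_flag`` marks the work_probability
    fraction of accepted/indicated trials that would lead to actual work.
    Fully reproducible under a fixed seed.
    """
    rng = _as_rng(rng, spec)
    params = draw_subject_parameters(spec, rng)
    latent = {(r.subject_id, r.condition): (r.bias, r.sigma) for r in params.itertuples()}

    rewards = np.asarray(design.reward_levels)
    offers = np.asarray(design.effort_offer_levels)
    trial_rows: list[dict] = []

    for sid in sorted({r for r, _ in latent}):
        # internal: reps_per_level indications per reward level
        bias, sigma = latent[(sid, "internal")]
        x_int = np.repeat(rewards, design.reps_per_level)
        latent_effort = design.max_effort * eval_sigmoid(x_int, bias, sigma)
        noise = rng.normal(0.0, spec.noise_sd * design.max_effort, size=x_int.shape)
        indicated = np.clip(latent_effort + noise, 0.0, design.max_effort)
        for x, e in zip(x_int, indicated):
            trial_rows.append(
                {
                    "subject_id": sid,
                    "condition": "internal",
                    "reward": float(x),
                    "offered_effort": np.nan,
                    "response": f"{e:.17g}",
                    "work_flag": bool(rng.random() < design.work_probability),
                }
            )
        # external: full reward x offer crossing, logistic accept rule
        bias, sigma = latent[(sid, "external")]
        for x in rewards:
            threshold = design.max_effort * eval_sigmoid(float(x), bias, sigma)
            p_accept = expit((threshold - offers) / spec.choice_temperature)
            accepted = rng.random(size=offers.shape) < p_accept
            for e, acc in zip(offers, accepted):
                trial_rows.append(
                    {
                        "subject_id": sid,
                        "condition": "external",
                        "reward": float(x),
                        "offered_effort": float(e),
                        "response": "Y" if acc else "N",
                        "work_flag": bool(acc and rng.random() < design.work_probability),
                    }
                )

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)

    # questionnaires: TEPS-anticipatory loads on internal bias; the
    # consummatory subscale and BDI are independent filler dimensions.
    internal_bias = params.query("condition == 'internal'").set_index("subject_id")["bias"]
    subjects = internal_bias.index.to_list()
    centered = internal_bias.to_numpy() - spec.bias_mean["internal"]
    teps_ant = (
        spec.teps_anticipatory_intercept
        + spec.teps_loading * centered
        + rng.normal(0.0, spec.teps_residual_sd, size=len(subjects))
    )
    quest = pd.DataFrame(
        {
            "subject_id": subjects,
            "teps_anticipatory": np.round(teps_ant, 2),
            "teps_consummatory": np.round(rng.normal(38.0, 6.0, size=len(subjects)), 2),
            "bdi": np.round(np.abs(rng.normal(8.0, 6.0, size=len(subjects)))),
        }
    )
    return trials, params, quest
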