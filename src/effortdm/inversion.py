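"""Single-subject model inversion: MAP estimation with a Laplace evidence.

Each effort curve is fit by maximizing the log joint (Gaussian likelihood
over curve points plus a Gaussian prior over unconstrained parameters)
with a quasi-Newton optimizer from several jittered starts.  The
posterior is the fixed-form Gaussian of the Laplace approximation: mean
at the MAP point, covariance the inverse negative Hessian there, and

    log_evidence = log_joint(map) + d/2 * log(2*pi) + 1/2 * log det(cov)

All fitting happens in unconstrained space (log links for positive
parameters), and the reported evidence is the marginal likelihood of that
parameterization — the prior is defined there, so no Jacobian correction
is applied when parameters are back-transformed for reporting.

The observation-noise log-SD is an auxiliary free parameter (prior
Normal(log 0.1, 1)) unless ``fixed_noise_sd`` pins it; it is excluded
from condition contrasts and recovery scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, optimize

from .curves import EffortCurve
from .models import ModelSpec, ParameterPoint, evaluate

__all__ = [
    "GroupPrior",
    "InversionOptions",
    "SubjectPosterior",
    "NOISE_NAME",
    "default_group_prior",
    "log_joint",
    "invert_subject",
    "compute_r_squared",
]

NOISE_NAME = "log_noise_sd"
LOG2 = np.log(2.0)
LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GroupPrior:
    """Gaussian population distribution over unconstrained parameters.

    Keys are unconstrained names (``bias``, ``log_sigma``, ...,
    ``log_noise_sd``).  Updated across empirical-Bayes iterations; the
    iteration index and the summed subject evidence at that iteration are
    carried for the convergence trace.
    """

    means: dict[str, float]
    variances: dict[str, float]
    iteration: int = 0
    group_log_evidence: float | None = None

    def __post_init__(self) -> None:
        if set(self.means) != set(self.variances):
            raise ValueError("means and variances must share keys")
        bad = {k: v for k, v in self.variances.items() if v <= 0}
        if bad:
            raise ValueError(f"prior variances must be > 0: {bad}")

    def vectors(self, names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        mu = np.array([self.means[n] for n in names])
        var = np.array([self.variances[n] for n in names])
        return mu, var

    def with_evidence(self, value: float, iteration: int) -> "GroupPrior":
        return replace(self, group_log_evidence=value, iteration=iteration)


def default_group_prior(model: ModelSpec, reward_scale: float = 1.0) -> GroupPrior:
    """Weak initial prior, centred for a reward axis of the given scale.

    ``reward_scale`` is roughly the midpoint of the reward range ($1 for
    the physical task, ~£100 for the cognitive ladder); translation-type
    parameters scale with it, shape parameters do not.
    """
    s = float(reward_scale)
    if model.family == "linear":
        means = {"m": 0.5 / s, "c": 0.0}
        variances = {"m": max(1.0, (1.0 / s) ** 2), "c": 1.0}
    elif model.family == "sigmoid":
        means = {"bias": s, "log_sigma": float(np.log(0.3 * s))}
        variances = {"bias": max(1.0, s**2), "log_sigma": 1.0}
    elif model.family == "weibull":
        means = {"log_A": float(np.log(0.8)), "log_L": float(np.log(1.0 / s)), "log_S": 0.0}
        variances = {"log_A": 0.25, "log_L": 1.0, "log_S": 1.0}
    else:
        raise ValueError(f"unknown family {model.family!r}")
    means[NOISE_NAME] = float(np.log(0.1))
    variances[NOISE_NAME] = 1.0
    return GroupPrior(means=means, variances=variances)


@dataclass(frozen=True)
class InversionOptions:
    n_restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 500
    hessian_step: float = 1e-5
    ridge: float = 1e-8
    ridge_warn: float = 1e-4
    fixed_noise_sd: float | None = None
    restart_seed: int = 0
    restart_scale: float = 1.0


@dataclass
class SubjectPosterior:
    """Gaussian parameter posterior for one curve, plus model evidence."""

    family: str
    subject_id: str
    condition: str
    names: tuple[str, ...]  # unconstrained names, in vector order
    mean: np.ndarray
    covariance: np.ndarray
    log_evidence: float
    r_squared: float
    converged: bool
    ridge_added: float = 0.0
    n_points: int = 0

    def natural_mean(self, model: ModelSpec) -> dict[str, float]:
        """Posterior mean back-transformed to natural space (incl. noise_sd)."""
        d_model = len(model.parameter_names)
        out = model.to_natural(self.mean[:d_model])
        if NOISE_NAME in self.names:
            out["noise_sd"] = float(np.exp(self.mean[self.names.index(NOISE_NAME)]))
        return out

    def to_record(self, model: ModelSpec) -> dict:
        rec = {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "model": self.family,
            "log_evidence": self.log_evidence,
            "r_squared": self.r_squared,
            "converged": self.converged,
        }
        rec.update(self.natural_mean(model))
        return rec


# ---------------------------------------------------------------------------
# model predictions and gradients in unconstrained space


def _predict_grad(model: ModelSpec, theta: np.ndarray, x: np.ndarray):
    """Prediction f(x) and Jacobian df/dtheta (n x d) in unconstrained space."""
    if model.family == "linear":
        m, c = theta
        f = m * x + c
        J = np.column_stack([x, np.ones_like(x)])
    elif model.family == "sigmoid":
        bias, u = theta
        sig = np.exp(np.clip(u, -300.0, 300.0))
        ceil = model.fixed.get("c", 1.0)
        z = (x - bias) / sig
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        f = ceil * s
        ds = ceil * s * (1.0 - s)
        J = np.column_stack([-ds / sig, -ds * z])
    elif model.family == "weibull":
        a, l, s_ = theta
        A, L, S = np.exp([a, l, s_])
        xl = x * L
        with np.errstate(divide="ignore"):
            log_xl = np.where(xl > 0, np.log(np.maximum(xl, 1e-300)), 0.0)
        t = np.where(xl > 0, np.exp(np.clip(S * log_xl, -700, 700)), 0.0)
        g = np.exp2(-np.minimum(t, 1e300))
        f = A * (1.0 - g)
        dfdt = A * LOG2 * g
        J = np.column_stack([f, dfdt * S * t, dfdt * S * log_xl * t])
    else:
        raise ValueError(f"unknown family {model.family!r}")
    return f, J


def _free_names(model: ModelSpec, opts: InversionOptions) -> tuple[str, ...]:
    names = model.unconstrained_names
    if opts.fixed_noise_sd is None:
        names = names + (NOISE_NAME,)
    return names


def _neg_log_joint_grad(theta, x, y, model, mu, var, fixed_noise_sd):
    d_model = len(model.parameter_names)
    th_model = theta[:d_model]
    if fixed_noise_sd is None:
        # floor keeps sd2 representable when the line search probes extremes
        ln_sd = max(theta[d_model], -300.0)
    else:
        ln_sd = np.log(fixed_noise_sd)
    sd2 = np.exp(2.0 * ln_sd)
    f, J = _predict_grad(model, th_model, x)
    r = y - f
    n = x.size
    ll = -0.5 * n * LOG_2PI - n * ln_sd - 0.5 * np.dot(r, r) / sd2
    grad = np.empty_like(theta)
    grad[:d_model] = J.T @ r / sd2
    if fixed_noise_sd is None:
        grad[d_model] = -n + np.dot(r, r) / sd2
    # Gaussian prior over all free parameters
    dev = theta - mu
    lp = -0.5 * np.sum(LOG_2PI + np.log(var)) - 0.5 * np.sum(dev**2 / var)
    grad -= dev / var
    return -(ll + lp), -grad


def log_joint(
    params,
    curve: EffortCurve,
    model: ModelSpec,
    prior: GroupPrior,
    opts: InversionOptions | None = None,
) -> float:
    """Log joint density of a curve and an unconstrained parameter point.

    ``params`` may be an unconstrained-space ParameterPoint (keyed by
    unconstrained names, plus ``log_noise_sd`` when the noise SD is free)
    or a plain vector in the layout ``model.unconstrained_names +
    (log_noise_sd,)``.
    """
    opts = opts or InversionOptions()
    names = _free_names(model, opts)
    if isinstance(params, ParameterPoint):
        if params.space_tag != "unconstrained":
            raise ValueError("log_joint expects unconstrained-space parameters")
        theta = np.array([params.values[n] for n in names], dtype=float)
    else:
        theta = np.asarray(params, dtype=float)
    if theta.shape != (len(names),):
        raise ValueError(f"expected {len(names)} parameters {names}, got shape {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter values")
    mu, var = prior.vectors(names)
    nll, _ = _neg_log_joint_grad(theta, curve.x, curve.y, model, mu, var, opts.fixed_noise_sd)
    return float(-nll)


def _fd_hessian(fun_grad, theta, rel_step):
    """Central-difference Hessian from the analytic gradient."""
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def invert_subject(
    curve: EffortCurve,
    model: ModelSpec,
    prior: GroupPrior,
    opts: InversionOptions | None = None,
) -> SubjectPosterior:
    """MAP fit of one model to one curve, with Laplace posterior and evidence.

    Runs a quasi-Newton optimizer from ``n_restarts`` starts (the prior
    mean, then prior-SD jitters of it) and keeps the best optimum; the
    negative-Hessian inverse at the optimum gives the posterior
    covariance, ridge-regularized until Cholesky succeeds.
    """
    opts = opts or InversionOptions()
    names = _free_names(model, opts)
    mu, var = prior.vectors(names)
    x, y = curve.x, curve.y

    def fun_grad(theta):
        return _neg_log_joint_grad(theta, x, y, model, mu, var, opts.fixed_noise_sd)

    rng = np.random.default_rng(opts.restart_seed)
    best = None
    any_success = False
    for k in range(opts.n_restarts):
        start = mu.copy()
        if k > 0:
            start = start + opts.restart_scale * np.sqrt(var) * rng.standard_normal(mu.size)
        res = optimize.minimize(
            fun_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts.max_iter, "gtol": opts.tol, "ftol": 1e-12},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta_hat = np.asarray(best.x, dtype=float)
    H = _fd_hessian(fun_grad, theta_hat, opts.hessian_step)  # Hessian of NEGATIVE log joint
    ridge = 0.0
    eye = np.eye(len(names))
    while True:
        try:
            chol = linalg.cholesky(H + ridge * eye, lower=True)
            break
        except linalg.LinAlgError:
            ridge = opts.ridge if ridge == 0.0 else ridge * 10.0
            if ridge > 1e6:
                # pathological curvature: fall back to the prior covariance
                chol = linalg.cholesky(np.diag(1.0 / var), lower=True)
                break
    cov = linalg.cho_solve((chol, True), eye)
    cov = 0.5 * (cov + cov.T)
    logdet_cov = -2.0 * np.sum(np.log(np.diag(chol)))
    lj = -float(best.fun)
    log_evidence = lj + 0.5 * len(names) * LOG_2PI + 0.5 * logdet_cov

    d_model = len(model.parameter_names)
    natural = model.to_natural(theta_hat[:d_model])
    r2 = compute_r_squared(curve, model, natural)
    converged = bool(any_success and np.isfinite(log_evidence))
    return SubjectPosterior(
        family=model.family,
        subject_id=curve.subject_id,
        condition=curve.condition,
        names=names,
        mean=theta_hat,
        covariance=cov,
        log_evidence=float(log_evidence),
        r_squared=r2,
        converged=converged,
        ridge_added=float(ridge),
        n_points=x.size,
    )


def compute_r_squared(curve: EffortCurve, model: ModelSpec, params: dict[str, float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of the fitted curve.

    Scale-invariant, so identical in normalized and raw effort units.
    Returns NaN (undefined-statistic flag) when the curve has zero
    variance.
    """
    y = curve.y
    yhat = np.asarray(evaluate(model, params, curve.x), dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot
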