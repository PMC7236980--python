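"""Random-effects Bayesian model selection (RFX-BMS) over log evidences.

The best-fitting model is treated as a random effect across subjects: a
Dirichlet distribution over population model frequencies is estimated by
the standard variational scheme, and summarized by

* expected model frequencies  alpha / sum(alpha),
* exceedance probability (EP) — the probability that a model is more
  frequent in the population than every competitor,
* Bayesian omnibus risk (BOR) — the posterior probability that evidence
  differences arose by chance (all models equally frequent),
* protected exceedance probability  PXP = EP * (1 - BOR) + BOR / K.

A between-conditions variant tests whether the same model governs both
motivation conditions: K^2 tuple models (model i in condition A, model j
in condition B) are compared, and the Dirichlet mass of the "same model"
family {(i, i)} is summarized at the family level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

__all__ = ["BMSResult", "rfx_bms", "between_conditions_bms"]


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over model frequencies with its summaries."""

    alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    bor: float
    protected_exceedance: np.ndarray
    mc_samples: int
    rng_seed: int | None
    model_names: tuple[str, ...] | None = None

    def __getitem__(self, name: str) -> dict[str, float]:
        if self.model_names is None:
            raise KeyError("no model names attached")
        k = self.model_names.index(name)
        return {
            "expected_frequency": float(self.expected_frequencies[k]),
            "exceedance": float(self.exceedance[k]),
            "protected_exceedance": float(self.protected_exceedance[k]),
        }


def _variational_dirichlet(log_ev: np.ndarray, alpha0: float, tol=1e-6, max_iter=10_000):
    """Iterate the Dirichlet updates to convergence; returns (alpha, u, F_rfx)."""
    n, K = log_ev.shape
    alpha = np.full(K, alpha0, dtype=float)
    a0 = np.full(K, alpha0, dtype=float)
    for _ in range(max_iter):
        w = log_ev + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    w = log_ev + digamma(alpha) - digamma(alpha.sum())
    u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
    # variational free energy of the Dirichlet model (at convergence the
    # alpha-stationarity term vanishes)
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    F = (
        float(np.sum(u * log_ev) - np.sum(ulogu))
        + gammaln(a0.sum())
        - gammaln(alpha.sum())
        + float(np.sum(gammaln(alpha) - gammaln(a0)))
        + float(np.dot(a0 - alpha + u.sum(axis=0), digamma(alpha) - digamma(alpha.sum())))
    )
    return alpha, u, F


def _exceedance(alpha: np.ndarray, mc_samples: int, rng) -> np.ndarray:
    """P(freq_k > freq_j for all j != k) under Dirichlet(alpha)."""
    K = alpha.size
    if K == 2:
        # f1 ~ Beta(a1, a2); P(f1 > 1/2) = 1 - I_{1/2}(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    draws = rng.dirichlet(alpha, size=mc_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=K) / mc_samples


def rfx_bms(
    log_evidences,
    alpha0: float = 1.0,
    mc_samples: int = 1_000_000,
    rng_seed: int | None = 0,
    model_names: tuple[str, ...] | None = None,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix.

    BOR compares the variational evidence of the Dirichlet (random
    frequencies) model against the equal-frequency null
    F_null = sum_n log mean_k exp(LE_nk):  bor = 1/(1 + exp(F_rfx - F_null)).
    Exceedance uses the closed Beta form when K = 2 and ``mc_samples``
    Dirichlet draws otherwise.
    """
    log_ev = np.asarray(log_evidences, dtype=float)
    if log_ev.ndim != 2 or log_ev.shape[0] < 1 or log_ev.shape[1] < 2:
        raise ValueError("log_evidences must be a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")
    n, K = log_ev.shape
    alpha, _, f_rfx = _variational_dirichlet(log_ev, alpha0)
    f_null = float(np.sum(logsumexp(log_ev, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(np.clip(f_rfx - f_null, -700, 700))))
    rng = np.random.default_rng(rng_seed)
    ep = _exceedance(alpha, mc_samples, rng)
    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=ep,
        bor=bor,
        protected_exceedance=pxp,
        mc_samples=mc_samples,
        rng_seed=rng_seed,
        model_names=model_names,
    )


def between_conditions_bms(
    log_evidences_a,
    log_evidences_b,
    alpha0: float = 1.0,
    mc_samples: int = 1_000_000,
    rng_seed: int | None = 0,
) -> dict:
    """Family-level stability test: same model in both conditions?

    Builds the K^2 tuple models with per-subject evidence
    LE_A[n, i] + LE_B[n, j], runs RFX-BMS over the tuples, and
    aggregates Dirichlet mass by family ("same" = the K diagonal tuples,
    "different" = the rest).  The family frequency is the summed member
    mass — a Beta marginal, so the family exceedance has a closed form —
    and the family PXP protects with the tuple-level BOR at the induced
    family prior (K of K^2 tuples, i.e. 1/K for "same").
    """
    le_a = np.asarray(log_evidences_a, dtype=float)
    le_b = np.asarray(log_evidences_b, dtype=float)
    if le_a.shape != le_b.shape:
        raise ValueError("condition evidence matrices must have identical shapes")
    n, K = le_a.shape
    tuples = le_a[:, :, None] + le_b[:, None, :]  # n x K x K
    log_ev = tuples.reshape(n, K * K)
    res = rfx_bms(log_ev, alpha0=alpha0, mc_samples=mc_samples, rng_seed=rng_seed)
    same_idx = [i * K + i for i in range(K)]
    diff_idx = [k for k in range(K * K) if k not in same_idx]
    a_same = float(res.alpha[same_idx].sum())
    a_diff = float(res.alpha[diff_idx].sum())
    ep_same = float(1.0 - betainc(a_same, a_diff, 0.5))
    prior_same = K / (K * K)
    pxp_same = ep_same * (1.0 - res.bor) + res.bor * prior_same
    return {
        "tuple_result": res,
        "same_family_frequency": a_same / (a_same + a_diff),
        "same_family_exceedance": ep_same,
        "bor": res.bor,
        "stability_pxp": pxp_same,
    }
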