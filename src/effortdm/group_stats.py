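"""Group-level inference on fitted parameters and questionnaire scores.

Paired t-tests contrast the internal and external conditions on
natural-space posterior means (bias in currency units, sigma in currency
units); Pearson correlations relate parameters to questionnaire scales
(TEPS anticipatory/consummatory, BDI); and Steiger's Z compares two
dependent correlations that share a variable (e.g. the TEPS-anticipatory
correlation of internal versus external bias).  All p values are
two-sided and reported uncorrected; an optional Bonferroni factor is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "CorrelationResult",
    "paired_t",
    "pearson_corr",
    "dependent_corr_diff",
    "condition_contrasts",
]


@dataclass(frozen=True)
class ContrastResult:
    parameter: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    z_diff: float | None = None
    p_diff: float | None = None


def paired_t(a, b, name: str = "") -> ContrastResult:
    """Two-sided paired-samples t-test on matched vectors a and b.

    Differences with zero variance but nonzero mean yield an infinite t
    with p = 0 (flagged by the infinite statistic) rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t needs two equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if md == 0.0 else float(np.inf) * np.sign(md)
        p = 1.0 if md == 0.0 else 0.0
    else:
        res = stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return ContrastResult(
        parameter=name, t_statistic=t, degrees_of_freedom=n - 1, p_value=p,
        mean_difference=md, n=n,
    )


def pearson_corr(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_corr needs two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic), p=float(res.pvalue), n=x.size)


def dependent_corr_diff(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate the shared variable with predictors 1 and
    2; ``r12`` is the correlation between the two predictors.  Uses the
    pooled-correlation form of the Fisher-z covariance (Steiger 1980,
    Z1*): two-sided p.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlations must lie strictly in (-1, 1), got {r}")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rm = 0.5 * (r1 + r2)
    rm2 = rm * rm
    # covariance of the two dependent correlations, pooled-r version
    psi = r12 * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r12 * r12)
    s = psi / ((1.0 - rm2) ** 2)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * s))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def condition_contrasts(
    posterior_table: pd.DataFrame,
    parameters: tuple[str, ...] = ("bias", "sigma"),
    bonferroni: bool = False,
) -> list[ContrastResult]:
    """Paired internal-vs-external contrasts from a tidy posterior table.

    Expects columns subject_id, condition, and one column per parameter
    (natural space).  Returns internal minus external contrasts; with
    ``bonferroni`` the p values are multiplied by the number of
    parameters tested (capped at 1).
    """
    wide = posterior_table.pivot_table(
        index="subject_id", columns="condition", values=list(parameters)
    )
    results = []
    for param in parameters:
        a = wide[(param, "internal")].to_numpy()
        b = wide[(param, "external")].to_numpy()
        res = paired_t(a, b, name=param)
        if bonferroni:
            res = ContrastResult(
                parameter=res.parameter,
                t_statistic=res.t_statistic,
                degrees_of_freedom=res.degrees_of_freedom,
                p_value=min(1.0, res.p_value * len(parameters)),
                mean_difference=res.mean_difference,
                n=res.n,
            )
        results.append(res)
    return results
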