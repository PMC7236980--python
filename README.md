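# effortdm

Effort-discounting psychometrics for the Internal–External Motivation Task
(IMT): a tested, reusable pipeline for dissociating **self-generated**
(internal) from **externally-generated** (external) motivation from
effort-for-reward choice data.

The package is aimed at computational-psychiatry researchers who collect
effort-based decision-making data — button presses (physical variant,
3–70 presses for \$0.25–\$2.00) or minutes of cognitive effort
(1–200 min for £1–£200) — and want the full modelling stack:

1. **Discount-curve preprocessing** — per subject and condition, trials are
   reduced to one normalized effort point per reward level (external: the
   maximum accepted effort offer; internal: the mean indicated effort).
2. **Psychometric curve fitting** — three candidate effort-by-reward
   functions are compared:

   - linear  `y = m·x + c`
   - sigmoid  `y = c / (1 + exp(−(x − bias)/σ))`  with asymptote fixed at
     `c = 1`, so its two free parameters are the **bias** (reward needed to
     reach half-maximal effort — bias away from initiating effort) and the
     inverse gradient **σ** (**reward insensitivity** — extra reward needed
     to accelerate effort)
   - Weibull  `y = A·(1 − 2^(−(x·L)^S))`

   Each curve is inverted by MAP estimation with a Laplace (fixed-form
   Gaussian) posterior and log evidence, inside an **iterated
   empirical-Bayes loop** that re-estimates the Gaussian group prior from
   the individual posteriors until the group-level evidence stops improving
   (both conditions pooled, which makes condition contrasts conservative).
3. **Random-effects Bayesian model selection** — Dirichlet variational
   updates over per-subject log evidences, with exceedance probability
   (EP), Bayesian omnibus risk (BOR) and protected exceedance probability
   `PXP = EP·(1 − BOR) + BOR/K`, plus a between-conditions **stability**
   test over the K² (condition-A model, condition-B model) tuple models.
4. **Simulation-recovery reliability** — draw parameters from the group
   distribution, simulate task data, re-invert, and report Pearson r
   between true and recovered values.
5. **Group statistics** — paired t contrasts between conditions,
   Pearson correlations with questionnaire scales (TEPS anticipatory /
   consummatory, BDI), and Steiger's Z for dependent correlations.

Because raw IMT datasets are not publicly deposited, the package ships a
first-class **synthetic cohort generator** that emulates both task
variants (latent sigmoid effort-reward curves with condition-specific
bias/insensitivity shifts, logistic accept/reject behaviour in the
external condition, Gaussian observation noise, questionnaire scores
loading on internal bias), so every stage is testable end to end.

## Worked example

```python
import effortdm as edm

design = edm.default_design("physical")          # 128 trials, 8 reward levels
spec = edm.default_cohort_spec("physical", rng_seed=1)
trials, truth, quest = edm.generate_cohort(design, spec)
curves = edm.curves_from_trials(trials, design)

evidence = {}
for family in ("linear", "sigmoid", "weibull"):
    prior, posts, trace = edm.fit_group(curves, edm.MODELS[family])
    for p in posts:
        evidence.setdefault(p.condition, {}).setdefault(family, {})[p.subject_id] = p.log_evidence

import numpy as np
subjects = sorted(evidence["internal"]["sigmoid"])
le = {c: np.array([[evidence[c][f][s] for f in ("linear", "sigmoid", "weibull")]
                   for s in subjects]) for c in evidence}
res = edm.rfx_bms(le["internal"] + le["external"], rng_seed=0,
                  model_names=("linear", "sigmoid", "weibull"))
print(np.round(res.expected_frequencies, 3))   # [0.035 0.929 0.036]
print(np.round(res.protected_exceedance, 3))   # [0.    1.    0.   ]
```

The sigmoid family — the one the cohort was generated from — takes an
estimated model frequency of 0.93 and a protected exceedance probability
of 1.0: with 26 subjects the Dirichlet mass is bounded near
(n + 1)/(n + 3) ≈ 0.93, and essentially all exceedance mass lands on the
sigmoid.

The same pipeline is available from the shell:

```bash
effortdm all --seed 1 --variant physical --out run1   # simulate → report
cat run1/report.md
```

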