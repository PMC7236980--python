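"""Synthetic IMT cohort generator: designs, cohorts, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import effortdm as edm


class TestDefaultDesign:
    def test_physical_structure(self, physical_design):
        d = physical_design
        assert d.n_trials == 128
        assert d.reward_levels[0] == pytest.approx(0.25)
        assert d.reward_levels[-1] == pytest.approx(2.00)
        assert len(d.reward_levels) == 8
        assert d.max_effort == 70
        assert d.work_probability == pytest.approx(0.30)

    def test_cognitive_structure(self, cognitive_design):
        d = cognitive_design
        assert max(d.reward_levels) == 200  # levels above £200 are excluded
        assert d.max_effort == 200
        assert d.reps_per_level == 1

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            edm.default_design("emotional")


class TestCohortSpec:
    def test_default_effect_direction(self):
        spec = edm.default_cohort_spec("physical")
        assert spec.bias_mean["internal"] > spec.bias_mean["external"]
        assert spec.log_sigma_mean["internal"] > spec.log_sigma_mean["external"]

    def test_null_switch_equalizes_conditions(self):
        null = edm.default_cohort_spec("physical", null=True)
        assert null.bias_mean["internal"] == null.bias_mean["external"]
        assert null.log_sigma_mean["internal"] == null.log_sigma_mean["external"]

    def test_validation(self):
        with pytest.raises(ValueError):
            edm.CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            edm.CohortSpec(choice_temperature=0.0)


class TestGenerateCohort:
    def test_trial_bookkeeping(self, small_cohort, physical_design):
        trials, params, quest = small_cohort
        assert len(trials) == 8 * physical_design.n_trials
        counts = trials.groupby(["subject_id", "condition"]).size()
        assert set(counts) == {64}
        assert set(trials["reward"].unique()) == set(physical_design.reward_levels)
        ext = trials[trials["condition"] == "external"]
        assert set(ext["offered_effort"].unique()) == set(physical_design.effort_offer_levels)
        assert set(ext["response"].unique()) <= {"Y", "N"}
        assert len(params) == 8 * 2
        assert len(quest) == 8

    def test_seed_reproducibility(self, physical_design):
        spec = edm.default_cohort_spec("physical", rng_seed=5)
        out1 = edm.generate_cohort(physical_design, spec)
        out2 = edm.generate_cohort(physical_design, spec)
        for a, b in zip(out1, out2):
            assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_work_flag_fraction(self, physical_design):
        spec = dataclasses.replace(edm.default_cohort_spec("physical"), n_subjects=30, rng_seed=2)
        trials, _, _ = edm.generate_cohort(physical_design, spec)
        internal = trials[trials["condition"] == "internal"]
        frac = internal["work_flag"].mean()
        n = len(internal)
        tol = 4 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.30) < tol

    def test_degenerate_cohort_matches_group_sigmoid(self, physical_design):
        """Zero SDs and zero noise: internal curves equal the mean sigmoid exactly;
        external curves match to within the offer-grid quantization."""
        base = edm.default_cohort_spec("physical")
        spec = dataclasses.replace(
            base,
            n_subjects=3,
            bias_sd={"internal": 0.0, "external": 0.0},
            log_sigma_sd={"internal": 0.0, "external": 0.0},
            noise_sd=0.0,
            choice_temperature=1e-9,
            rng_seed=0,
        )
        trials, params, _ = edm.generate_cohort(physical_design, spec)
        curves = edm.curves_from_trials(trials, physical_design)
        x = np.asarray(physical_design.reward_levels)
        for curve in curves:
            mu_b = spec.bias_mean[curve.condition]
            mu_s = float(np.exp(spec.log_sigma_mean[curve.condition]))
            truth = edm.eval_sigmoid(x, mu_b, mu_s)
            if curve.condition == "internal":
                np.testing.assert_allclose(curve.y, truth, atol=1e-12)
            else:
                grid_step = np.diff(physical_design.effort_offer_levels).max()
                thresh = physical_design.max_effort * truth
                offers = np.asarray(physical_design.effort_offer_levels)
                expected = [
                    max([o for o in offers if o < t], default=0.0) for t in thresh
                ]
                np.testing.assert_allclose(
                    curve.y, np.asarray(expected) / physical_design.max_effort, atol=1e-9
                )
                assert np.all(np.abs(curve.y - truth) <= (grid_step + 1) / physical_design.max_effort)

    def test_acceptance_monotone_in_offer_and_reward(self, physical_design):
        """Pooled acceptance rates fall with offered effort, rise with reward."""
        spec = dataclasses.replace(
            edm.default_cohort_spec("physical"),
            n_subjects=150,
            bias_sd={"internal": 0.0, "external": 0.0},
            log_sigma_sd={"internal": 0.0, "external": 0.0},
            rng_seed=9,
        )
        trials, _, _ = edm.generate_cohort(physical_design, spec)
        ext = trials[trials["condition"] == "external"].copy()
        ext["accept"] = (ext["response"] == "Y").astype(float)
        by_offer = ext.groupby("offered_effort")["accept"].mean()
        by_reward = ext.groupby("reward")["accept"].mean()
        slack = 0.05  # binomial noise at n = 150*8 per cell
        assert np.all(np.diff(by_offer.to_numpy()) < slack)
        assert np.all(np.diff(by_reward.to_numpy()) > -slack)


def test_true_bias_marginal_is_gaussian():
    """KS test of generated bias draws against the specified population."""
    spec = dataclasses.replace(edm.default_cohort_spec("physical"), n_subjects=5000, rng_seed=17)
    params = edm.draw_subject_parameters(spec)
    internal = params.query("condition == 'internal'")["bias"]
    res = stats.kstest(
        internal, "norm", args=(spec.bias_mean["internal"], spec.bias_sd["internal"])
    )
    assert res.pvalue > 0.01
    log_sigma = np.log(params.query("condition == 'external'")["sigma"])
    res2 = stats.kstest(
        log_sigma, "norm", args=(spec.log_sigma_mean["external"], spec.log_sigma_sd["external"])
    )
    assert res2.pvalue > 0.01


def test_questionnaire_loading_direction():
    """TEPS-anticipatory correlates negatively with internal bias by construction."""
    spec = dataclasses.replace(edm.default_cohort_spec("physical"), n_subjects=200, rng_seed=3)
    design = edm.default_design("physical")
    _, params, quest = edm.generate_cohort(design, spec)
    internal = params.query("condition == 'internal'").set_index("subject_id")["bias"]
    merged = quest.set_index("subject_id").join(internal)
    r = np.corrcoef(merged["bias"], merged["teps_anticipatory"])[0, 1]
    assert r < -0.2
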