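"""MAP inversion, Laplace evidence, and r-squared."""

import numpy as np
import pytest
from scipy import stats

import effortdm as edm
from effortdm.inversion import NOISE_NAME, GroupPrior, InversionOptions
from effortdm.models import ParameterPoint


def _curve(x, y):
    return edm.EffortCurve("s1", "internal", tuple(x), tuple(y), len(x))


WEAK = GroupPrior(
    means={"bias": 1.0, "log_sigma": np.log(0.3), NOISE_NAME: np.log(0.1)},
    variances={"bias": 4.0, "log_sigma": 4.0, NOISE_NAME: 1.0},
)


class TestLogJoint:
    def test_term_by_term_arithmetic(self):
        """Agreement with an independent sum of normal log-densities."""
        curve = _curve([0.5, 1.5], [0.3, 0.7])
        theta = np.array([0.9, np.log(0.4), np.log(0.08)])
        got = edm.log_joint(theta, curve, edm.SIGMOID, WEAK)
        f = edm.eval_sigmoid(curve.x, 0.9, 0.4)
        expected = stats.norm.logpdf(curve.y, f, 0.08).sum()
        mu, var = WEAK.vectors(("bias", "log_sigma", NOISE_NAME))
        expected += stats.norm.logpdf(theta, mu, np.sqrt(var)).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_accepts_parameter_point(self):
        curve = _curve([0.5, 1.5], [0.3, 0.7])
        pp = ParameterPoint(
            {"bias": 0.9, "log_sigma": float(np.log(0.4)), NOISE_NAME: float(np.log(0.08))},
            "unconstrained",
        )
        vec = np.array([0.9, np.log(0.4), np.log(0.08)])
        assert edm.log_joint(pp, curve, edm.SIGMOID, WEAK) == pytest.approx(
            edm.log_joint(vec, curve, edm.SIGMOID, WEAK)
        )

    def test_nonfinite_rejected(self):
        curve = _curve([0.5, 1.5], [0.3, 0.7])
        with pytest.raises(ValueError):
            edm.log_joint(np.array([np.nan, 0.0, 0.0]), curve, edm.SIGMOID, WEAK)

    def test_maximized_at_prior_mean_for_consistent_data(self, physical_design):
        """Noise-free data generated at the prior mean: gradient vanishes there."""
        x = np.asarray(physical_design.reward_levels)
        y = edm.eval_sigmoid(x, WEAK.means["bias"], np.exp(WEAK.means["log_sigma"]))
        curve = _curve(x, y)
        opts = InversionOptions(fixed_noise_sd=0.05)
        center = np.array([WEAK.means["bias"], WEAK.means["log_sigma"]])
        base = edm.log_joint(center, curve, edm.SIGMOID, WEAK, opts)
        for delta in np.eye(2) * 1e-3:
            assert edm.log_joint(center + delta, curve, edm.SIGMOID, WEAK, opts) < base
            assert edm.log_joint(center - delta, curve, edm.SIGMOID, WEAK, opts) < base


class TestInvertSubject:
    def test_recovers_noise_free_truth(self, sigmoid_curve):
        post = edm.invert_subject(sigmoid_curve, edm.SIGMOID, WEAK)
        nat = post.natural_mean(edm.SIGMOID)
        assert nat["bias"] == pytest.approx(1.0, abs=1e-3)
        assert nat["sigma"] == pytest.approx(0.3, abs=1e-3)
        assert post.converged

    def test_degenerate_prior_pins_posterior(self, sigmoid_curve):
        tight = GroupPrior(
            means={"bias": 0.4, "log_sigma": np.log(0.2), NOISE_NAME: np.log(0.1)},
            variances={"bias": 1e-12, "log_sigma": 1e-12, NOISE_NAME: 1e-12},
        )
        post = edm.invert_subject(sigmoid_curve, edm.SIGMOID, tight)
        assert post.mean[0] == pytest.approx(0.4, abs=1e-4)
        assert post.mean[1] == pytest.approx(np.log(0.2), abs=1e-4)

    def test_prior_shift_moves_argmax_when_likelihood_flat(self, sigmoid_curve):
        """With an (almost) flat likelihood the MAP tracks the prior mean."""
        opts = InversionOptions(fixed_noise_sd=1e6)
        for shift in (0.0, 0.7):
            prior = GroupPrior(
                means={"bias": 1.0 + shift, "log_sigma": np.log(0.3), NOISE_NAME: np.log(0.1)},
                variances={"bias": 1.0, "log_sigma": 1.0, NOISE_NAME: 1.0},
            )
            post = edm.invert_subject(sigmoid_curve, edm.SIGMOID, prior, opts)
            assert post.mean[0] == pytest.approx(1.0 + shift, abs=1e-4)

    def test_restart_stability(self, sigmoid_curve):
        """The MAP point is identical across restart seeds on a convex instance."""
        ref = edm.invert_subject(
            sigmoid_curve, edm.SIGMOID, WEAK, InversionOptions(restart_seed=0)
        )
        for seed in (1, 2):
            alt = edm.invert_subject(
                sigmoid_curve, edm.SIGMOID, WEAK, InversionOptions(restart_seed=seed)
            )
            np.testing.assert_allclose(alt.mean, ref.mean, atol=1e-6)

    def test_evidence_identity(self, sigmoid_curve):
        """log_evidence decomposes as log_joint(MAP) + Gaussian volume term."""
        post = edm.invert_subject(sigmoid_curve, edm.SIGMOID, WEAK)
        lj = edm.log_joint(post.mean, sigmoid_curve, edm.SIGMOID, WEAK)
        d = len(post.names)
        vol = 0.5 * d * np.log(2 * np.pi) + 0.5 * np.linalg.slogdet(post.covariance)[1]
        assert post.log_evidence == pytest.approx(lj + vol, abs=1e-6)

    def test_quadrature_oracle(self, physical_design):
        """Laplace evidence within 0.05 nats of brute-force 2-D quadrature."""
        x = np.asarray(physical_design.reward_levels)
        rng = np.random.default_rng(4)
        y = np.clip(edm.eval_sigmoid(x, 1.1, 0.35) + rng.normal(0, 0.05, x.size), 0, 1)
        curve = _curve(x, y)
        opts = InversionOptions(fixed_noise_sd=0.05)
        post = edm.invert_subject(curve, edm.SIGMOID, WEAK, opts)
        sds = np.sqrt(np.diag(post.covariance))
        grids = [np.linspace(m - 4 * s, m + 4 * s, 241) for m, s in zip(post.mean, sds)]
        lj = np.empty((grids[0].size, grids[1].size))
        for i, b in enumerate(grids[0]):
            for j, u in enumerate(grids[1]):
                lj[i, j] = edm.log_joint(np.array([b, u]), curve, edm.SIGMOID, WEAK, opts)
        peak = lj.max()
        inner = np.trapezoid(np.exp(lj - peak), grids[1], axis=1)
        quad = peak + np.log(np.trapezoid(inner, grids[0]))
        assert post.log_evidence == pytest.approx(quad, abs=0.05)

    def test_occam_prefers_true_simpler_model(self, physical_design):
        """Linear data: extra Weibull flexibility is penalized by the evidence."""
        x = np.asarray(physical_design.reward_levels)
        rng = np.random.default_rng(8)
        y = np.clip(0.15 + 0.3 * x + rng.normal(0, 0.02, x.size), 0, 1)
        curve = _curve(x, y)
        lin = edm.invert_subject(curve, edm.LINEAR, edm.default_group_prior(edm.LINEAR))
        wei = edm.invert_subject(curve, edm.WEIBULL, edm.default_group_prior(edm.WEIBULL))
        assert lin.log_evidence > wei.log_evidence


class TestRSquared:
    def test_perfect_and_constant_fits(self, sigmoid_curve):
        assert edm.compute_r_squared(
            sigmoid_curve, edm.SIGMOID, {"bias": 1.0, "sigma": 0.3}
        ) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # y = {0.1, 0.5, 0.9}, yhat = {0.2, 0.5, 0.8}: 1 - 0.02/0.32
        curve = _curve([0.5, 1.0, 1.5], [0.1, 0.5, 0.9])
        # linear with m=0.6, c=-0.1 predicts exactly {0.2, 0.5, 0.8}
        r2 = edm.compute_r_squared(curve, edm.LINEAR, {"m": 0.6, "c": -0.1})
        assert r2 == pytest.approx(0.9375)

    def test_zero_variance_flagged(self):
        curve = _curve([0.5, 1.0], [0.4, 0.4])
        assert np.isnan(edm.compute_r_squared(curve, edm.LINEAR, {"m": 0.0, "c": 0.4}))
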