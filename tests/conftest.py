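import numpy as np
import pytest

import effortdm as edm


@pytest.fixture(scope="session")
def physical_design():
    return edm.default_design("physical")


@pytest.fixture(scope="session")
def cognitive_design():
    return edm.default_design("cognitive")


@pytest.fixture(scope="session")
def small_cohort(physical_design):
    """An 8-subject physical cohort: trials, true parameters, questionnaires."""
    spec = edm.default_cohort_spec("physical", rng_seed=11)
    spec = spec.__class__(**{**spec.to_dict(), "n_subjects": 8})
    return edm.generate_cohort(physical_design, spec)


@pytest.fixture(scope="session")
def sigmoid_curve(physical_design):
    """A noise-free sigmoid effort curve at the 8 physical reward levels."""
    x = np.asarray(physical_design.reward_levels)
    y = edm.eval_sigmoid(x, bias=1.0, sigma=0.3)
    return edm.EffortCurve(
        subject_id="s0", condition="internal",
        rewards=tuple(x), efforts=tuple(y), n_raw_trials=len(x),
    )


@pytest.fixture(scope="session")
def fast_opts():
    """Reduced-restart inversion options for heavier simulation tests."""
    return edm.InversionOptions(n_restarts=2)
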