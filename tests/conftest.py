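import numpy as np
import pytest

import vocdecode as vd


@pytest.fixture(scope="session")
def tiny_space():
    return vd.make_source_space(16, seed=0)


@pytest.fixture(scope="session")
def tiny_leadfield(tiny_space):
    return vd.make_leadfield(tiny_space, 8, seed=0)


@pytest.fixture(scope="session")
def null_session(tiny_space, tiny_leadfield):
    """One fast simulated session with zero planted effects."""
    eff = vd.materialize_effect(
        vd.EffectSpec(a_content=0, a_prod=0, a_late=0, a_effort=0, a_cue=0),
        tiny_space, seed=5)
    design = vd.build_session_design("T1", 1, 7)
    return vd.simulate_session(design, eff, vd.NoiseSpec(), tiny_leadfield,
                               seed=3, sfreq=20.0)


@pytest.fixture(scope="session")
def effect_session(tiny_space, tiny_leadfield):
    """One simulated session with the default planted effects."""
    eff = vd.materialize_effect(vd.EffectSpec(), tiny_space, seed=5)
    design = vd.build_session_design("T1", 1, 7)
    return vd.simulate_session(design, eff, vd.NoiseSpec(), tiny_leadfield,
                               seed=3, sfreq=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
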