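import numpy as np
import pytest

from nocicalc import SimWellConfig, StimulationProtocol, simulate_well

#: standard double-stimulation protocol used across tests: HBSS control at 10 s,
#: P2X3-agonist-like stimulus A at 20 s, TRPV1-agonist-like stimulus B at 32 s
STIMULI = {"HBSS": 10.0, "stimA": 20.0, "stimB": 32.0}


@pytest.fixture
def protocol() -> StimulationProtocol:
    # the baseline window covers the final 5 s of the pre-stimulus period so it
    # matches the re-anchored baselines of later stimuli frame-for-frame
    return StimulationProtocol(
        stimuli=tuple(sorted(STIMULI.items(), key=lambda kv: kv[1])),
        baseline_window=(5.0, 10.0),
        response_window_length=8.0,
        rebaseline_length=5.0,
    )


@pytest.fixture
def small_well():
    cfg = SimWellConfig(n_cells=40, stimulus_times=STIMULI, seed=7)
    traces, truths = simulate_well(cfg)
    return cfg, traces, truths


def well_config(**overrides) -> SimWellConfig:
    """A SimWellConfig with the standard stimuli, overridable per test."""
    kwargs = dict(stimulus_times=STIMULI)
    kwargs.update(overrides)
    return SimWellConfig(**kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
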