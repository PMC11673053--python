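import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photoperant import AgentConfig, PhotometryGenConfig, TaskConfig
from photoperant import events as ev
from photoperant import simulate as sim

settings.register_profile(
    "suite", deadline=None, max_examples=40, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_agent():
    return AgentConfig()


@pytest.fixture(scope="session")
def default_pcfg():
    return PhotometryGenConfig()


@pytest.fixture(scope="session")
def phase1_session(default_agent):
    """A trained-regime classical-conditioning session (day 8)."""
    task = TaskConfig(phase="I")
    log, truth = sim.run_task_state_machine(
        task, default_agent, day=8, test_index=1,
        rng=np.random.default_rng(101))
    return task, log, truth


@pytest.fixture(scope="session")
def phase2_session(default_agent):
    """A mid-training free-operant session (day 4)."""
    task = TaskConfig(phase="II")
    log, truth = sim.run_task_state_machine(
        task, default_agent, day=4, test_index=1,
        rng=np.random.default_rng(102))
    return task, log, truth


@pytest.fixture(scope="session")
def phase2_processed(phase2_session, default_pcfg):
    """The same session with photometry generated and normalized."""
    from photoperant import photometry as ph

    task, log, truth = phase2_session
    rec, truth = sim.generate_photometry(
        log, truth, default_pcfg, rng=np.random.default_rng(103))
    trace = ph.process_recording(rec)
    trials = ev.segment_trials(log)
    return log, truth, rec, trace, trials
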