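import numpy as np
import pytest

from escapekit.kinematics import KinematicParams, ThreatSpec, generate_epoch_scenario
from escapekit.simulate import AgentPolicy, DelayLaw, simulate_epoch
from escapekit.vocalization import synth_audio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return KinematicParams()


@pytest.fixture
def fast_threat():
    return ThreatSpec("dog", speed=-3.0, is_chasing=True, is_faster_than_participant=True)


@pytest.fixture
def slow_threat():
    return ThreatSpec("snake", speed=-1.0, is_chasing=True)


@pytest.fixture
def rock():
    return ThreatSpec("rock", speed=-3.0, is_chasing=False)


@pytest.fixture
def attack_scenario(fast_threat):
    rng = np.random.default_rng(7)
    return generate_epoch_scenario(fast_threat, "attack", "short", rng, approach_angle=-45.0)


@pytest.fixture
def divert_scenario(fast_threat):
    rng = np.random.default_rng(8)
    return generate_epoch_scenario(fast_threat, "divert", "long", rng, approach_angle=-45.0)


@pytest.fixture
def textbook_epoch(attack_scenario):
    """A clean simulated escape: instant initiation, fast enough to reach shelter."""
    rng = np.random.default_rng(99)
    policy = AgentPolicy(
        initiation_delay_law=DelayLaw("constant", 0.2),
        escape_speed=2.0,
        fruit_pick_rate=0.8,
    )
    return simulate_epoch(attack_scenario, policy, rng)


@pytest.fixture(scope="session")
def labeled_audio():
    clips, labels = synth_audio(120, rng=np.random.default_rng(42))
    return clips, labels
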