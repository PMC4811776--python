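import numpy as np
import pytest

from hierdcm.design import InputTimeline
from hierdcm.modelspace import ModelSpec
from hierdcm.simulate import DCMParameters


def two_node_timeline(rng: np.random.Generator, n_scans: int, dt: float = 0.5, trial_soa: float = 2.0) -> InputTimeline:
    """Random two-channel impulse train: one impulse per trial on one of
    two driving channels."""
    spt = int(round(trial_soa / dt))
    T = n_scans * spt
    drive = np.zeros((T, 2))
    mod = np.zeros((T, 0))
    for tr in range(n_scans):
        drive[tr * spt, rng.integers(2)] = 1.0
    return InputTimeline(dt=dt, drive=drive, mod=mod, trial_soa=trial_soa,
                         drive_names=("u1", "u2"), mod_names=())


TWO_NODE_SPEC = ModelSpec(
    regions=("R1", "R2"),
    edges=(("R1", "R2"),),
    drive_targets=(("u1", "R1"), ("u2", "R2")),
    modulations=(),
)


def two_node_params(a12: float, a21: float, self_decay: float = -0.5) -> DCMParameters:
    A = np.array([[self_decay, a12], [a21, self_decay]])
    return DCMParameters(("R1", "R2"), A, {}, np.eye(2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_design():
    from hierdcm.design import generate_design

    return generate_design(seed=0, protocol={"sessions": 1, "runs_per_session": 1, "blocks_per_run": 16})
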