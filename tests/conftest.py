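import numpy as np
import pytest

from polfx.exchange_simulator import SimulationConfig, simulate_dataset
from polfx.polymer_models import ElasticityParams, reconstruct_junction


@pytest.fixture(scope="session")
def params():
    return ElasticityParams()


#: Fixed-seed simulation used by the detector-quality tests: balanced
#: exo/pol force schedule (junction stays mid-frame, no template clipping),
#: dwells long enough for pauses to be resolvable at the default smoothing.
DETECTOR_CONFIG = dict(
    seed=7,
    duration=200.0,
    bp_init=5000,
    p_pause_given_bind=0.35,
    tau_off=4.0,
    k_on=0.5,
    force_schedule=((0.0, 50.0), (50.0, 20.0), (100.0, 50.0), (150.0, 20.0)),
)


@pytest.fixture(scope="session")
def detector_sim(params):
    cfg = SimulationConfig(**DETECTOR_CONFIG)
    truth, trace, kymo = simulate_dataset(cfg, params)
    traj = reconstruct_junction(trace, params)
    return cfg, truth, trace, kymo, traj


def interval_overlap(a, b):
    return min(a[1], b[1]) - max(a[0], b[0])


def matched(interval, candidates):
    return any(interval_overlap(interval, c) > 0 for c in candidates)
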