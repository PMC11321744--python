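import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pursuit3d import simulator as sim

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: The eight corner-direction labels: the only spawn directions whose
#: trajectories excite all three spherical dimensions (r, theta, phi).
CORNER_LABELS = ("lnt", "lnb", "rnb", "rnt", "lft", "lfb", "rfb", "rft")


@pytest.fixture(scope="session")
def perfect_corner_trials():
    """Noise-free pursuit of each corner-direction linear target, single
    visible object, near and far distances (16 trials)."""
    logs = []
    for dist in (0.4, 1.4):
        for i, lab in enumerate(CORNER_LABELS):
            cfg = sim.TrialConfig(target=lab, movement="linear", center_distance=dist,
                                  object_labels=(lab,), seed=100 + i,
                                  trial_id=f"perfect-{dist:g}-{lab}")
            logs.append(sim.simulate_trial(cfg, sim.NOISE_FREE))
    return logs


@pytest.fixture(scope="session")
def noisy_corner_block():
    """26 noisy linear trials over four corner objects (typical tracker noise)."""
    cond = sim.TrialConfig(target="lnt", movement="linear",
                           object_labels=CORNER_LABELS[:4], visible=CORNER_LABELS[:4])
    return sim.simulate_block([cond], n_rounds=7, seed=202,
                              eye=sim.OculomotorParams(angular_noise_sd=0.5))
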