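import numpy as np
import pytest

import hepregen as h


@pytest.fixture(scope="session")
def ref():
    """Human-timescale optimized reference parameter set."""
    return h.id71_optimal()


@pytest.fixture(scope="session")
def rat():
    """Synthetic rodent-baseline stand-in (calibration initial guess)."""
    return h.rat_baseline()


@pytest.fixture(scope="session")
def ref_traj(ref):
    """Reference 2/3-hepatectomy trajectory over the 2.5-year window."""
    return h.simulate_resection(ref, 2.0 / 3.0, horizon=912.5)


def jittered_params(ref, rng, names=("M", "k_G", "beta_ap"), fold=2.0):
    """Reference set with log-uniform fold jitter on the given parameters."""
    return ref.replace(
        **{n: float(getattr(ref, n) * fold ** rng.uniform(-1, 1)) for n in names}
    )
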