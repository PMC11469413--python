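import numpy as np
import pytest

from organics import CircuitParams

# Printed 2D phase-portrait parameter sets: shared b=0.5, tau=2 ms, w=1, z=1;
# (a) contractive recurrence, (b) expansive with small semisaturation,
# (c) expansive with large semisaturation.
PORTRAIT_SETS = {
    "contractive": dict(wr=0.5, b0=0.5, sigma=0.1),
    "expansive-small-sigma": dict(wr=2.0, b0=0.5, sigma=0.1),
    "expansive-large-sigma": dict(wr=2.0, b0=1.0, sigma=1.0),
}


def portrait_params(name: str) -> CircuitParams:
    cfg = PORTRAIT_SETS[name]
    return CircuitParams(n=1, tau_y=2.0, tau_a=2.0, b=0.5, b0=cfg["b0"],
                         sigma=cfg["sigma"], W_r=[[cfg["wr"]]], W=[[1.0]])


@pytest.fixture
def scalar_params() -> CircuitParams:
    """The worked n=1 identity-recurrence example: b=b0=0.5, sigma=0.1, w=1."""
    return CircuitParams(n=1, tau_y=2.0, tau_a=2.0, b=0.5, b0=0.5, sigma=0.1,
                         W_r=[[1.0]], W=[[1.0]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
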