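import numpy as np
import pytest

from f1rotary.simulate import MotorScheme, Pause, simulate_trace


@pytest.fixture(scope="session")
def tf1_geometry_scheme():
    """Six pauses per turn, sub 40 degrees after main: a/b = 0.5."""
    return MotorScheme(
        pauses=(Pause(0.0, 1e-3, "binding"), Pause(80.0, 10e-3, "catalytic")),
        noise_sd=8.0,
    )


@pytest.fixture(scope="session")
def bmf1_geometry_scheme():
    """Six pauses per turn, sub midway between mains: a/b = 1.0."""
    return MotorScheme(
        pauses=(Pause(0.0, 10e-3, "catalytic"), Pause(60.0, 1e-3, "short")),
        noise_sd=8.0,
    )


@pytest.fixture(scope="session")
def staircase():
    """Noiseless 3-level staircase [0 x50, 120 x50, 240 x50]."""
    return np.repeat([0.0, 120.0, 240.0], 50)


@pytest.fixture(scope="session")
def short_tf1_trace(tf1_geometry_scheme):
    """A 3-second TF1-geometry trace shared across detection tests."""
    return simulate_trace(tf1_geometry_scheme, 3.0, 10_000.0, seed=42)
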