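import numpy as np
import pytest

from putkit.bubble import BubbleTrajectory, MediumProperties
from putkit.threshold import DriveProtocol


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    """Default blood/water-like medium shared across simulation tests."""
    return MediumProperties()


@pytest.fixture(scope="session")
def fast_protocol() -> DriveProtocol:
    """Short-burst drive recipe for desk-scale threshold searches."""
    return DriveProtocol(cycles=32)


def synthetic_trajectory(
    x: np.ndarray, t: np.ndarray, R0: float = 100e-9, freq: float | None = 1e6
) -> BubbleTrajectory:
    """Wrap a hand-built R/R0 series into a trajectory object."""
    return BubbleTrajectory(
        time_s=t,
        radius_m=R0 * x,
        velocity_m_s=np.gradient(R0 * x, t),
        initial_radius_m=R0,
        drive_frequency_Hz=freq,
        status=0,
        n_steps=0,
    )
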