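import numpy as np
import pytest

from piuptake.kinetics import RadialIntensityLaw
from piuptake.synthetic import CellField, TraceSet, render_stack, simulate_traces


@pytest.fixture(scope="session")
def paper_law() -> RadialIntensityLaw:
    """The experiment's fitted plateau law, 321 + 228/γ AU."""
    return RadialIntensityLaw.from_coefficients(321.0, 228.0)


@pytest.fixture(scope="session")
def small_field() -> CellField:
    """A hand-placed field of well-separated cells around a central bead.

    Positions keep every 2×1 µm rod at least 4 µm from its neighbours and
    from the bead, so footprints never overlap and ROI recovery is exact up
    to rasterisation.
    """
    positions = np.array(
        [
            [10.0, 10.0], [20.0, 10.0], [30.0, 10.0], [40.0, 10.0], [50.0, 10.0],
            [10.0, 20.0], [20.0, 20.0], [40.0, 20.0], [50.0, 20.0],
            [10.0, 30.0], [50.0, 30.0],
            [10.0, 40.0], [20.0, 40.0], [40.0, 40.0], [50.0, 40.0],
            [10.0, 50.0], [20.0, 50.0], [30.0, 50.0], [40.0, 50.0], [50.0, 50.0],
        ]
    )
    return CellField(
        positions=positions,
        fov_size=60.0,
        density=len(positions) / 60.0**2,
        bead_positions=np.array([[30.0, 30.0]]),
        bead_radius=1.5,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(small_field, paper_law):
    import pandas as pd

    from piuptake.synthetic import assign_ground_truth

    return assign_ground_truth(small_field, law=paper_law, k_mean=0.0046,
                               k_sd=0.0015, R_max=29.7, seed=3)


@pytest.fixture(scope="session")
def rendered(small_field, noiseless_truth):
    """Noiseless rendered stack (delay 0, so the first frame is background-free)."""
    traces = simulate_traces(noiseless_truth, dt=10.0, n_frames=30, delay=0.0,
                             noise_sd=0.0, seed=0)
    stack = render_stack(small_field, traces, pixel_size=223.5 / 1024, seed=1)
    return stack, traces
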