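import numpy as np
import pytest

from sonocell.acoustics import IMAGING_CONTEXT, PCD_CONTEXT
from sonocell.bubble_dynamics import BubbleParams
from sonocell.scene import KIND_BUBBLE, KIND_TISSUE, Scene


@pytest.fixture(scope="session")
def imaging_context():
    return IMAGING_CONTEXT


@pytest.fixture(scope="session")
def pcd_context():
    return PCD_CONTEXT


def point_scene(
    kind: int = KIND_TISSUE,
    position=(0.0, 5e-3),
    reflectivity: float = 1.0,
    bubble_params: BubbleParams | None = None,
    x_limits=(-1.5e-3, 1.5e-3),
    z_limits=(3.4e-3, 6.6e-3),
) -> Scene:
    """Scene with a single scatterer, for point-target tests."""
    if kind == KIND_BUBBLE and bubble_params is None:
        from sonocell.config import default_phagocytosed_bubble

        bubble_params = default_phagocytosed_bubble()
    return Scene(
        positions=np.array([position], dtype=float),
        reflectivity=np.array([reflectivity], dtype=float),
        kind=np.array([kind], dtype=np.int8),
        velocities=np.zeros((1, 2)),
        x_limits=x_limits,
        z_limits=z_limits,
        bubble_params=bubble_params,
    )
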