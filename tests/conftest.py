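import numpy as np
import pytest

from vessel3d.synthetic import generate_phantom, render_stack, slice_phantom


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(seed=1, n_bifurcations=2)


@pytest.fixture(scope="session")
def mask_stack(phantom):
    return slice_phantom(phantom, thickness_um=4.0, pixel_um=0.28)


@pytest.fixture(scope="session")
def rendered(mask_stack):
    return render_stack(mask_stack, stain_style="he", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
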