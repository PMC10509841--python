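import numpy as np
import pytest

from cptquant.synthetic import EyePhantomSpec, phantom_grid, render_eye_image


@pytest.fixture(scope="session")
def default_spec():
    return EyePhantomSpec()


@pytest.fixture(scope="session")
def clean_render(default_spec):
    """One straight-gaze phantom render with its ground truth."""
    return render_eye_image(default_spec, "straight")


@pytest.fixture(scope="session")
def fixture_grid():
    """The fixed 20-phantom validation grid (specs only; images rendered
    lazily by the tests that need them)."""
    return phantom_grid(20)


@pytest.fixture(scope="session")
def flat_spec():
    """Phantom with no redness sources and no noise: the sclera is a single
    uniform color after gain/exposure."""
    return EyePhantomSpec(vessel_count=0, diffuse_redness=0.0, noise_sd=0.0)
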