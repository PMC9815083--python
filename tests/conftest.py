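import numpy as np
import pytest

from picophys import CellSpec, GeneratorConfig, render_phase_image
from picophys.qpi import ALPHA_BEAD, N_BEAD, N_MEDIUM


@pytest.fixture
def noiseless_cfg() -> GeneratorConfig:
    """Generator with all stochastic terms off and sub-frame quantization."""
    return GeneratorConfig(ks_cv=0.0, noise_cv=0.0,
                           consecutive_division_rate=0.0,
                           frame_interval=0.001, events_per_level=10, seed=0)


@pytest.fixture
def bead_spec() -> CellSpec:
    """The 1 um polystyrene calibration bead of the control experiment."""
    return CellSpec(length=1.0, width=1.0,
                    density=(N_BEAD - N_MEDIUM) / ALPHA_BEAD,
                    refraction_increment=ALPHA_BEAD, position=(2.0, 2.0))


@pytest.fixture
def bead_image(bead_spec):
    return render_phase_image([bead_spec], pixel_size=0.045,
                              image_shape=(90, 90), noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
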