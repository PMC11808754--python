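import numpy as np
import pytest

from fastpass.io import default_layout
from fastpass.sim import (
    AnalytePanelEntry,
    NoiseModel,
    RateResponseModel,
    simulate_run,
)


@pytest.fixture
def small_layout():
    """5-spot array: samples at 1/3/5, solvent blanks at 2/4, 20 mm scan."""
    return default_layout(
        5,
        spot_width=2000.0,
        span=18_000.0,
        margin=1000.0,
        roles=["sample", "solvent_blank", "sample", "solvent_blank", "sample"],
    )


@pytest.fixture
def single_analyte(small_layout):
    return AnalytePanelEntry(
        name="C12:0",
        formula="C12H24O2",
        adduct="[M-H]-",
        base_intensity=1000.0,
        spatial_profile="uniform",
        spot_labels=["Spot 3"],
    )


@pytest.fixture
def quiet_noise():
    return NoiseModel(baseline_level=0.0, baseline_dispersion=0.0, seed=0)


@pytest.fixture
def no_deloc_model():
    return RateResponseModel(delocalization_level=0.0)


@pytest.fixture
def clean_run(small_layout, single_analyte, quiet_noise, no_deloc_model):
    """Noiseless, delocalization-free run with one analyte in Spot 3."""
    return simulate_run(
        small_layout,
        [single_analyte],
        rate=50.0,
        pixel_size=50.0,
        rate_model=no_deloc_model,
        noise=quiet_noise,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
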