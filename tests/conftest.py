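import numpy as np
import pytest

from engramecho.synthgen import (
    CalciumModel,
    GeneratorConfig,
    StimulationPattern,
    generate_raster,
)


@pytest.fixture(scope="session")
def single_3hz_pattern():
    return StimulationPattern(kind="single", frequency=3.0)


@pytest.fixture(scope="session")
def doublet_pattern():
    return StimulationPattern(kind="doublet", doublet_isi=0.16, pattern_period=0.46)


@pytest.fixture(scope="session")
def small_recording(single_3hz_pattern):
    """20 cells, 3 Hz stimulation, some reverberation; shared read-only."""
    cfg = GeneratorConfig(
        n_cells=20, seed=2, reverb_fraction=0.3, background_rate=0.5
    )
    return generate_raster(cfg, single_3hz_pattern)


@pytest.fixture(scope="session")
def noiseless_model():
    return CalciumModel(noise_sd=0.0)
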