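import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fgmtools import CORTISOL, PipelineConfig
from fgmtools.simulate import default_extractions, simulate_plate


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def clean_plate():
    """Noiseless 7-standard cortisol plate with 5 mid-curve samples."""
    concs = [(f"S{i}", c) for i, c in enumerate((300.0, 600.0, 1200.0, 2400.0, 4800.0), 1)]
    plate, truth = simulate_plate(concs, CORTISOL, seed=0)
    return plate, truth


@pytest.fixture
def clean_plate_files(tmp_path, clean_plate):
    from fgmtools import write_plate

    plate, truth = clean_plate
    layout = tmp_path / "layout.csv"
    od = tmp_path / "od.csv"
    write_plate(plate, str(layout), str(od))
    return layout, od, plate, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
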