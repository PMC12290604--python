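import numpy as np
import pytest

import lamvaso as lv


@pytest.fixture()
def acq() -> lv.AcquisitionScheme:
    return lv.AcquisitionScheme()


@pytest.fixture(scope="session")
def noise_free_model() -> lv.CompartmentModel:
    return lv.CompartmentModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def participant(noise_free_model) -> "lv.workflows.Participant":
    """Noise-free default-grid participant, 4 long-ITI runs."""
    return lv.simulate_participant(n_runs=4, iti_class="long", seed=11,
                                   model=noise_free_model)


@pytest.fixture(scope="session")
def analysis(participant) -> dict:
    """Full pipeline output (run-average, upsample, BOCO, ERAs, metrics)."""
    return lv.analyze_participant(participant)


@pytest.fixture(scope="session")
def small_geometry() -> lv.GeometryLabels:
    """Small annulus for fast simulation tests (no layering involved)."""
    return lv.build_geometry(grid_shape=(30, 30, 4), annulus_radii=(6.0, 10.0),
                             n_vessels=2, seed=5)
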