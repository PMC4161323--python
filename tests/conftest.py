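from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def species_rows():
    from seasens import ssi
    return ssi.load_species_scores()


@pytest.fixture(scope="session")
def expected_collision():
    return pd.read_csv(DATA / "collision_expected.csv")


@pytest.fixture(scope="session")
def expected_displacement():
    return pd.read_csv(DATA / "displacement_expected.csv")


@pytest.fixture(scope="session")
def hotspot_study():
    """The bundled hotspot scenario: coastline, grid, truth, scenario (seed 0)."""
    from seasens import synthetic
    return synthetic.standard_hotspot_scenario(seed=0)


@pytest.fixture(scope="session")
def hotspot_recovery(hotspot_study):
    """One full survey → detection → DSM run on the bundled scenario."""
    from seasens import pipeline
    land, grid, truth, scenario = hotspot_study
    return pipeline.run_hotspot_recovery(truth, scenario, grid,
                                         coastline=land, seed=0)
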