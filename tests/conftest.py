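import numpy as np
import pytest

from chromofold import (PipelineConfig, PolymerParams, make_fixture,
                        run_pipeline, sample_null_ensemble)


@pytest.fixture(scope="session")
def loose_params():
    """Roomy geometry for fast, rarely-dead-ending growth."""
    return PolymerParams(confinement_radius=300.0)


@pytest.fixture(scope="session")
def desk_params():
    """Density-derived confinement for a 500-kb locus (the desk fixture)."""
    return PolymerParams().with_radius_for(500_000)


@pytest.fixture(scope="session")
def small_null(desk_params):
    """A modest null ensemble on 30 bins shared across caller tests."""
    return sample_null_ensemble(desk_params, 30, 400, seed=123)


@pytest.fixture(scope="session")
def desk_fixture():
    """The canonical desk-scale synthetic study (100 bins, 12 contacts)."""
    return make_fixture(seed=7)


@pytest.fixture(scope="session")
def desk_pipeline(desk_fixture):
    """Full pipeline run on the desk fixture (shared; dominates suite time)."""
    return run_pipeline(desk_fixture.target_hic, desk_fixture.params, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
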