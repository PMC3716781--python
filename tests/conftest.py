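import pytest

from biofacets.dynamics_classifier import (
    EXCITABLE_SWITCH,
    LIMIT_CYCLE_OSCILLATION,
    STABLE_FIXED_POINT,
    ClassificationProtocol,
)
from biofacets.tyson_fixtures import (
    find_regime_parameters,
    taxonomy_fragment,
    tyson_model1,
    tyson_model2,
)


@pytest.fixture(scope="session")
def model1_bundle():
    return tyson_model1()


@pytest.fixture(scope="session")
def model2_bundle():
    return tyson_model2()


@pytest.fixture(scope="session")
def protocol_v():
    """Default protocol with the cyclin-pool variable as excitability trigger."""
    return ClassificationProtocol(perturb_symbol="v")


@pytest.fixture(scope="session")
def taxonomy():
    return taxonomy_fragment()


@pytest.fixture(scope="session")
def model2_regime_points(model2_bundle):
    """Seeded regime points of the two-variable model, one per dynamics class."""
    return {
        label: find_regime_parameters(model2_bundle.model, label, seed=1)
        for label in (STABLE_FIXED_POINT, LIMIT_CYCLE_OSCILLATION, EXCITABLE_SWITCH)
    }
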