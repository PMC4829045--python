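import pytest
from hypothesis import HealthCheck, settings

from skeletochron.core import BackCalcParams
from skeletochron.pipeline import run_pipeline
from skeletochron.study import make_study_fixture

# reproducible, database-free hypothesis runs
settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> BackCalcParams:
    return BackCalcParams()


@pytest.fixture(scope="session")
def study_fixture():
    """(records, profiles) realised from the published study's printed tables."""
    return make_study_fixture()


@pytest.fixture(scope="session")
def study_result(study_fixture):
    records, profiles = study_fixture
    return run_pipeline(records, profiles)
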