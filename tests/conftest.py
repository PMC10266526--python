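import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from archintro import meta_analysis as meta          # noqa: E402
from archintro import synthetic_data as synth        # noqa: E402
from archintro import introgression as intro         # noqa: E402


@pytest.fixture(scope="session")
def study():
    """The default simulated study (panel, archaic reference, cohort,
    three studies' summary statistics) under the standard conditions."""
    return synth.build_fixture({"seed": 7})


@pytest.fixture(scope="session")
def meta_results(study):
    stacked = meta.intersect_studies(study.sumstats)
    return meta.meta_analyze(stacked)


@pytest.fixture(scope="session")
def called_tracts(study):
    return intro.call_tracts(study.panel, study.archaic, study.rec_map)
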