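import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from hiddenhunger import (
    ConversionPolicy,
    attach_daly_indices,
    compute_prevalence_indices,
    harmonize,
    synthetic_appendix,
    worked_example,
)


@pytest.fixture(scope="session")
def policy():
    return ConversionPolicy()


@pytest.fixture(scope="session")
def appendix():
    """Synthetic stand-in for the per-country appendix tables."""
    return synthetic_appendix()


@pytest.fixture(scope="session")
def appendix_results(appendix):
    """Full pipeline run on the appendix stand-in: (included, excluded,
    merged index results)."""
    countries, dalys = appendix
    included, excluded = harmonize(countries)
    results = compute_prevalence_indices(included)
    results = attach_daly_indices(results, dalys, {r.iso3: r for r in countries})
    return included, excluded, results


@pytest.fixture(scope="session")
def worked():
    return worked_example()
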