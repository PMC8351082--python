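import pytest

from strscreen.catalog import catalog_by_id, default_catalog
from strscreen.ensemble import CVScheme
from strscreen.harmonize import binarize_all, build_labeled_matrix
from strscreen.synthetic import (default_tool_profiles, ega_like_config,
                                 simulate_cohort)

SIX_TOOLS = ("eh_v2", "eh_v3", "gangstr", "tredparse", "stretch", "exstra")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def by_id(catalog):
    return catalog_by_id(catalog)


@pytest.fixture(scope="session")
def ega_cohort(catalog):
    """Benchmark-like cohort: 86 expansion carriers + 32 unaffected."""
    config = ega_like_config(seed=11)
    return simulate_cohort(config, default_tool_profiles(), catalog)


@pytest.fixture(scope="session")
def ega_matrix(ega_cohort, by_id):
    unified = binarize_all(
        ega_cohort.genotype_calls + ega_cohort.outlier_results, by_id)
    return build_labeled_matrix(unified, ega_cohort.truth, SIX_TOOLS)


@pytest.fixture(scope="session")
def fast_scheme():
    """Smaller CV scheme for unit tests where 50 splits are not the point."""
    return CVScheme(k=5, repeats=2, seed=7)
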