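import pytest

from citrinspec import (
    build_allele_count_fixture,
    build_genotype_count_fixture,
    dedupe_families,
    load_default_region_map,
    load_default_registry,
    load_packaged_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def region_map():
    return load_default_region_map()


@pytest.fixture(scope="session")
def cohort(registry, region_map):
    return load_packaged_cohort(region_map, registry)


@pytest.fixture(scope="session")
def families(cohort):
    return dedupe_families(cohort)


@pytest.fixture(scope="session")
def allele_fixture():
    """Region-stratified allele counts rebuilt from published frequencies."""
    return build_allele_count_fixture()


@pytest.fixture(scope="session")
def genotype_fixture():
    """Region-stratified genotype counts rebuilt from published frequencies."""
    return build_genotype_count_fixture()
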