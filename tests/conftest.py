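import pytest

from biochipscreen import (
    NoiseModel,
    default_models,
    default_panel,
    generate_validation_cohort,
    validate_panel,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def validation_records(panel, models, noise):
    """One seeded 20+20 validation cohort for all 15 analytes."""
    return generate_validation_cohort(panel, models, noise, seed=0)


@pytest.fixture(scope="session")
def validation_report(validation_records, panel):
    return validate_panel(validation_records, panel)
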