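import pytest

from easi import ModelConstants, ParameterSet, builtin_parameters


@pytest.fixture
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture
def scenario1() -> ParameterSet:
    return builtin_parameters("scenario-1")


@pytest.fixture
def never_smoker() -> ParameterSet:
    """Never-smoker whose age-20 FEV1 coincides with the reference anchor."""
    return ParameterSet(
        smoker=False,
        age_smoking_onset=None,
        max_exposure=0.0,
        time_to_max_exposure=None,
        fev1_at_20=4.0,
    )
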