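import pytest

from repeatst.synthetic_data import GeneratorConfig, generate_st


@pytest.fixture
def default_st():
    """One default synthetic ST precursor (noise 0) with its truth."""
    return generate_st(GeneratorConfig(seed=1))


@pytest.fixture
def iia_family():
    """Ten type-IIa precursors with distinct seeds."""
    return [generate_st(GeneratorConfig(seed=s, st_type="IIa")) for s in range(10)]
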