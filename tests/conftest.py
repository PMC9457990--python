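import pytest

from aptevolve.energetics import build_energy_model, load_energy_parameters


@pytest.fixture(scope="session")
def energy_model():
    """Default DNA model (37 degC, 1 M Na+), shared across the suite."""
    return build_energy_model()


@pytest.fixture(scope="session")
def parameter_set():
    return load_energy_parameters()
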