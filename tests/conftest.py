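import numpy as np
import pytest

from memtherm.synthetic import (default_series_spec, default_thermogram_spec,
                                generate_nitroxide_spectrum,
                                generate_two_component_series,
                                generate_two_state_thermogram)


@pytest.fixture(scope="session")
def noiseless_thermogram():
    """DPPC-like two-state endotherm, no noise, with pretransition."""
    return generate_two_state_thermogram(default_thermogram_spec())


@pytest.fixture(scope="session")
def noiseless_series():
    """Noiseless coexistence series with its exact ground truth and the
    pure-component basis spectra."""
    spec = default_series_spec()
    spectra, truth = generate_two_component_series(spec)
    bases = (generate_nitroxide_spectrum(spec.ordered_model, spec.field_grid),
             generate_nitroxide_spectrum(spec.disordered_model,
                                         spec.field_grid))
    return spec, spectra, truth, bases


@pytest.fixture(scope="session")
def field_grid():
    return np.linspace(3250.0, 3450.0, 1024)
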