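import numpy as np
import pytest

from neomrs.core import AcquisitionGrid
from neomrs.quant import LinearCombinationModel
from neomrs.simulate import (CohortConfig, baseline_concentrations,
                             default_basis, generate_cohort,
                             simulate_spectrum)


@pytest.fixture(scope="session")
def grid():
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def cortex_conc():
    return baseline_concentrations("cortex")


@pytest.fixture(scope="session")
def noiseless_pair(cortex_conc):
    """Noiseless spectrum + water reference with known nuisances."""
    return simulate_spectrum(cortex_conc, 31.5, noise_sd=0.0, damping_hz=10.1,
                             phase0=0.1, shift_ppm=0.02)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_pair, basis):
    spec, _ = noiseless_pair
    return LinearCombinationModel(spec, basis).fit(compute_uncertainty=False,
                                                   noise_sd=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic default-size cohort without phantoms (fast)."""
    return generate_cohort(CohortConfig(seed=11, make_phantoms=False))
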