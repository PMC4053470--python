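import numpy as np
import pytest

from genometab import simulate


@pytest.fixture(scope="session")
def peaks():
    return simulate.default_peak_specs()


@pytest.fixture(scope="session")
def snps():
    return simulate.default_snp_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """n=150 cohort with spectra; shared across tests that only read it."""
    return simulate.gen_cohort(150, seed=42, make_spectra=True)


@pytest.fixture(scope="session")
def mid_cohort():
    """n=600 cohort without spectra, for statistics-heavy tests."""
    return simulate.gen_cohort(600, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
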