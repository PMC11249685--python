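import numpy as np
import pytest

import spectromics as sp
from spectromics.pipeline import patient_fingerprints


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but class-separable cohort for fast end-to-end tests."""
    cfg = sp.CohortConfig(
        n_control=5, n_oa=5, samples_per_patient=1, spectra_per_sample=4,
        seed=11,
    )
    return sp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fingerprints(small_cohort):
    """Fingerprint matrices, labels, patients and fused objects."""
    return patient_fingerprints(small_cohort)


@pytest.fixture(scope="session")
def default_cohort_fingerprints():
    """One full-size default cohort carried through preprocessing/fusion."""
    cohort = sp.generate_cohort(sp.CohortConfig(seed=3))
    return patient_fingerprints(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def raman_spectrum(intensities, axis=None):
    """Helper: wrap intensities in a Raman Spectrum on a matching axis."""
    intensities = np.asarray(intensities, dtype=float)
    if axis is None:
        axis = np.linspace(1722.0, 614.0, intensities.size)
    return sp.Spectrum(
        wavenumbers=np.asarray(axis, dtype=float),
        intensities=intensities,
        modality=sp.RAMAN,
    )
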