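import numpy as np
import pandas as pd
import pytest

from aquaphot.spectra_io import SpectraSet
from aquaphot.synthetic import generate_cohort, preset


def make_spectra(absorbance, wavelengths=None, labels=None, specimen="plasma",
                 subjects=None):
    """Small hand-built SpectraSet for unit tests."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n = absorbance.shape[0]
    if wavelengths is None:
        wavelengths = 1300.0 + 0.5 * np.arange(absorbance.shape[1])
    if labels is None:
        labels = ["healthy"] * n
    if subjects is None:
        subjects = [f"s{i:02d}" for i in range(n)]
    meta = pd.DataFrame({
        "id": [f"{s}:{i}" for i, s in enumerate(subjects)],
        "subject_id": subjects,
        "replicate": [1] * n,
        "specimen": [specimen] * n,
        "label3": labels,
    })
    return SpectraSet(np.asarray(wavelengths, dtype=float), absorbance, meta)


@pytest.fixture(scope="session")
def plasma_cohort():
    """Strong-separation plasma cohort: 13 subjects x 3 replicates."""
    return generate_cohort(preset("plasma_ibd", seed=17))


@pytest.fixture(scope="session")
def saliva_cohort():
    return generate_cohort(preset("saliva_ibd", seed=17))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(preset("null", seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
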