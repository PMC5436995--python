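import pytest

from petdosim import load_reference_bundle
from petdosim.io import clinical_dose_report, load_clinical_reference


@pytest.fixture(scope="session")
def bundle():
    return load_reference_bundle()


@pytest.fixture(scope="session")
def nuclide(bundle):
    return bundle.nuclide


@pytest.fixture(scope="session")
def phantom_male(bundle):
    return bundle.phantoms["male"]


@pytest.fixture(scope="session")
def phantom_female(bundle):
    return bundle.phantoms["female"]


@pytest.fixture(scope="session")
def clinical():
    return load_clinical_reference()


@pytest.fixture(scope="session")
def male_30min_report():
    """Published male organ-dose column for the 30-min voiding cycle."""
    return clinical_dose_report("dose_male_30min")
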