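import warnings

import pytest

from gdsirt.banks import reference_bank, reference_scales
from gdsirt.irt import TwoPLModel
from gdsirt.simulate import CohortConfig, generate_cohort, stratified_split


@pytest.fixture(scope="session")
def bank():
    return reference_bank()


@pytest.fixture(scope="session")
def scales():
    return reference_scales()


@pytest.fixture(scope="session")
def cohort():
    """One default-condition synthetic cohort (n=6525, prevalence ~3.8%)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def halves(cohort):
    return stratified_split(cohort, 0.5, 21)


@pytest.fixture(scope="session")
def dev_fit(halves):
    """2PL calibration on the development half, with item AUCs attached."""
    dev, _ = halves
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = TwoPLModel(dev.responses).fit()
    res.attach_item_aucs(dev.diagnosis)
    return res
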