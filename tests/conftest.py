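import numpy as np
import pytest

from leupkpd import Dose, params
from leupkpd.synthetic import DRUG_SAMPLING_H


@pytest.fixture(scope="session")
def drug_times():
    """The in vivo sampling schedule of the drug-treated groups (hours)."""
    return np.asarray(DRUG_SAMPLING_H)


@pytest.fixture(scope="session")
def iv_dose():
    return Dose.from_nominal(
        params.NOMINAL_DOSE_MG_PER_KG, params.DEFAULT_BODY_WEIGHT_KG, "IV"
    )


@pytest.fixture(scope="session")
def sc_dose():
    return Dose.from_nominal(
        params.NOMINAL_DOSE_MG_PER_KG, params.DEFAULT_BODY_WEIGHT_KG, "SC-solution"
    )


@pytest.fixture(scope="session")
def depot_dose():
    return Dose.from_nominal(
        params.NOMINAL_DOSE_MG_PER_KG, params.DEFAULT_BODY_WEIGHT_KG, "SC-depot"
    )
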