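import numpy as np
import pytest

import fluoxpk as fx


@pytest.fixture(scope="session")
def final_model():
    return fx.builtin_model("FINAL")


@pytest.fixture(scope="session")
def m1_model():
    return fx.builtin_model("M1")


@pytest.fixture(scope="session")
def m2_model():
    return fx.builtin_model("M2")


@pytest.fixture(scope="session")
def default_cohort():
    """The 198-subject study-design cohort at the canonical test seed."""
    return fx.generate_cohort(fx.CohortDesign(seed=0))


@pytest.fixture(scope="session")
def female_typical(final_model):
    return fx.individual_parameters(final_model, {"SEX": 0})


#: day-30 trough oracle values for the joint model, computed by independent
#: high-accuracy ODE integration of the depot/parent/metabolite system
#: (60 mg QD x 30 doses, trough just before dose 31)
ORACLE_F60 = {"parent": 251.3245, "metabolite": 238.5402, "active_moiety": 489.8647}
ORACLE_M60_ACTIVE = 362.7410


@pytest.fixture(scope="session")
def oracle_f60():
    return ORACLE_F60
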