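import pytest

from qalytree import om85


@pytest.fixture(scope="session")
def om85_model():
    return om85.build_om85_model()


@pytest.fixture(scope="session")
def base_outcomes(om85_model):
    return om85_model.outcomes()


# Hand path enumeration at the published base values:
#   placebo: cost = 0.2*2022; qaly = 0.8*0.94 + 0.2*(0.992*0.87 + 0.008*0)
#   om85:    repeat prob 0.2*(1-0.65)=0.07; cost = 74 + 0.07*2022;
#            qaly = 0.93*0.94 + 0.07*(0.992*0.87)
PLACEBO_COST = 404.40
PLACEBO_QALY = 0.924608
OM85_COST = 215.54
OM85_QALY = 0.9346128
WTP = 5180.0
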