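import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# peptides of the study system: two 12-mer CXCR4-antagonist derivatives
# with a free Cys at position 10, and the Cys34-bearing tryptic fragment
# of the albumin mature chain (residues 21-41)
WSC02 = "IVRWSKKVPCVS"
JM21 = "ILRWSRKLPCVS"
ALBUMIN_21_41 = "ALVLIAFAQYLQQCPFEDHVK"
# mature-chain neighborhood of the Cys34 fragment (residues 1-51)
ALBUMIN_1_51 = "DAHKSEVAHRFKDLGEENFK" + ALBUMIN_21_41 + "LVNEVTEFAK"


@pytest.fixture
def wsc02():
    return WSC02


@pytest.fixture
def jm21():
    return JM21


@pytest.fixture
def albumin_fragment():
    return ALBUMIN_21_41
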