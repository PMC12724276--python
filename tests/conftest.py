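import pytest

from hicas12a.pam import builtin_profile
from hicas12a.seqcore import LocusSequence


@pytest.fixture(scope="session")
def implb():
    return builtin_profile("impLbCas12a")


@pytest.fixture(scope="session")
def wt_lb():
    return builtin_profile("LbCas12a")


@pytest.fixture()
def tiny_locus():
    """Locus with exactly one TTTC PAM (plus spacer room) on the + strand."""
    # 4-nt PAM + 23-nt spacer fits; no other recognizable canonical PAM.
    seq = "GAGAGAGAGAGA" + "TTTC" + "GACGACGAGGACGAGGACGAGGA" + "GAGAGAGAGAG"
    return LocusSequence("tiny", seq, frame_start=0)
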