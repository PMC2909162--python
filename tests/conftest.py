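import numpy as np
import pytest

from trigdx import SubjectRecord

# The three published worked clinical cases: bilateral masseter amplitudes
# in mV, reference (painful) side first, and the published outcome.
CLINICAL_CASES = {
    "case1": dict(record=SubjectRecord("case1", jj_ip_ref=0.0,
                                       jj_ip_contra=1.0,
                                       mep_ref=0.672, mep_contra=3.0),
                  mep_ratio=0.672 / 3.0, jj_ratio=None,
                  label="ORGANIC_DAMAGE", step=1),
    "case2": dict(record=SubjectRecord("case2", jj_ip_ref=3.0,
                                       jj_ip_contra=3.3,
                                       mep_ref=8.0, mep_contra=10.3),
                  mep_ratio=8.0 / 10.3, jj_ratio=3.0 / 3.3,
                  label="OP", step=2),
    "case3": dict(record=SubjectRecord("case3", jj_ip_ref=0.329,
                                       jj_ip_contra=1.5,
                                       mep_ref=3.4, mep_contra=3.5),
                  mep_ratio=3.4 / 3.5, jj_ratio=0.329 / 1.5,
                  label="TMD", step=2),
}


@pytest.fixture
def clinical_cases():
    return CLINICAL_CASES


@pytest.fixture
def rng():
    return np.random.default_rng(20101)
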