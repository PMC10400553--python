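import pytest

from cilioscreen.classify import classify_cohort
from cilioscreen.simulate import ReferenceCohort, generate_reference_cohort


@pytest.fixture(scope="session")
def refcohort() -> ReferenceCohort:
    return generate_reference_cohort()


@pytest.fixture(scope="session")
def refcohort_classified(refcohort):
    tiered, counts = classify_cohort(refcohort.calls, refcohort.whitelist)
    return tiered, counts
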