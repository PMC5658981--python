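import pytest

from mavt.datasets import load_case_study
from mavt.model import AdditiveValueModel


@pytest.fixture(scope="session")
def mcrc():
    """The packaged mCRC case study (precise one-decimal weights)."""
    return load_case_study()


@pytest.fixture(scope="session")
def mcrc_fitted():
    """Fitted evaluation of the mCRC case study."""
    return AdditiveValueModel.from_case_study().fit()
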