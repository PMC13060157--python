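import numpy as np
import pytest

from annotaudit import synthetic_data as syn
from annotaudit.readprep import AdapterSpec


@pytest.fixture(scope="session")
def small_transcriptome():
    """20 sharp-TSS transcripts on a toy chromosome, with depth weights."""
    return syn.make_transcriptome(n_transcripts=20, seed=7)


@pytest.fixture
def adapter_spec():
    return AdapterSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
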