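import numpy as np
import pytest

from niswitch import EntrySpec, GenGammaSpec, scale_from_median


@pytest.fixture
def rng():
    return np.random.default_rng(20240607)


@pytest.fixture
def exp_median1() -> GenGammaSpec:
    return scale_from_median(1.0)


@pytest.fixture
def exp_median6() -> GenGammaSpec:
    return scale_from_median(6.0)


@pytest.fixture
def uniform_entry3() -> EntrySpec:
    return EntrySpec(pattern="unif", accrual_duration=3.0)
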