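import numpy as np
import pytest

from liverdwi.signal_models import (
    BiExpParams,
    BValueScheme,
    StretchedExpParams,
)

# Published group-level ground truths used as round-trip anchors throughout
# the suite (BA-group values; units mm^2/s).
BA_BEM = BiExpParams(S0=1.0, D=0.835e-3, Dstar=33.2e-3, f=0.134)
FIG1_SEM = StretchedExpParams(S0=1.0, DDC=0.839e-3, alpha=0.757)
BA_ADC2 = 0.987e-3


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
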