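import numpy as np
import pytest

# Reported P-values for 11 mu-opioid receptor SNPs (pain sensitivity),
# the package's worked example.
TABLE8 = np.array([0.0007, 0.0941, 0.2957, 0.7037, 0.8171, 0.8012,
                   0.5745, 0.9891, 0.8308, 0.8208, 0.3139])


@pytest.fixture
def table8():
    return TABLE8.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20190920)
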