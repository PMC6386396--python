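import numpy as np
import pytest

from shmax import corpus as cm
from shmax.cochlea import build_filterbank, cochleogram
from shmax.model import SHMAX, compact_architecture


@pytest.fixture(scope="session")
def filterbank_small():
    """A reduced 64-channel bank over the standard 73-7,630 Hz span."""
    return build_filterbank(64, 73.0, 7630.0, 16000.0)


@pytest.fixture(scope="session")
def inventory():
    return cm.make_inventory(8, seed=7)


@pytest.fixture(scope="session")
def corpus_small(inventory):
    """60-token synthetic corpus: (waveform, transcript, ground truth)."""
    return cm.synthesize(inventory, 60, jitter_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def cochleogram_small(corpus_small, filterbank_small):
    wav, _, _ = corpus_small
    return cochleogram(wav, filterbank_small)


@pytest.fixture(scope="session")
def fitted_small(cochleogram_small):
    """A small fitted 4-layer network on the 60-token corpus."""
    arch = compact_architecture(n_maps=(12, 12, 16, 16))
    return SHMAX([cochleogram_small], arch).fit(n_patches=600, epochs=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
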