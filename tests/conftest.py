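import numpy as np
import pytest

from microstates import synth


@pytest.fixture(scope="session")
def templates64():
    return synth.make_templates(64, 4, "well_separated", seed=11)


@pytest.fixture(scope="session")
def templates8():
    return synth.make_templates(8, 4, "well_separated", seed=7)


@pytest.fixture(scope="session")
def noiseless_subject(templates64):
    """Six noiseless 2-s epochs with planted four-class dynamics."""
    spec = synth.DynamicsSpec(n_epochs=6, snr=np.inf)
    eps, gt = synth.simulate_subject(templates64, spec, seed=21)
    return eps, gt, templates64


@pytest.fixture(scope="session")
def noisy_subject(templates64):
    """Eight epochs at the default SNR of 4."""
    spec = synth.DynamicsSpec(n_epochs=8, snr=4.0)
    eps, gt = synth.simulate_subject(templates64, spec, seed=22)
    return eps, gt, templates64


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """True at samples adjacent to a planted segment boundary."""
    mask = np.zeros(labels.shape, dtype=bool)
    d = np.diff(labels, axis=1) != 0
    mask[:, 1:] |= d
    mask[:, :-1] |= d
    return mask
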